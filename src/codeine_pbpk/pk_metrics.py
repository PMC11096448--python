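"""Non-compartmental analysis and fold-error model evaluation.

NCA computes AUC by the linear-up/log-down trapezoid rule, the terminal
slope lambda_z by log-linear regression over the candidate terminal window
(>= 3 points after Tmax) with the best adjusted R-squared, and extrapolates
AUC to infinity as AUC_0-t + C_last/lambda_z.

Model evaluation follows the fold-error convention: MFE = predicted /
observed per parameter, GMFE = 10**(mean |log10 MFE|), and a model is
accepted when mean MFE and GMFE lie within the 0.5- to 2-fold range for
every parameter.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PKSummary", "FoldErrorReport", "nca",
    "mfe", "gmfe", "fold_fraction", "evaluate_model",
    "read_observed", "write_observed",
]

OBSERVED_COLUMNS = ["study_id", "analyte", "time_h", "conc_ng_per_ml"]


@dataclass(frozen=True)
class PKSummary:
    """NCA parameters of one concentration-time profile."""

    auc_0_t: float                     # ng*h/mL
    auc_0_inf: float | None            # None when no terminal slope estimable
    cmax: float                        # ng/mL
    tmax_h: float
    lambda_z_per_h: float | None
    half_life_h: float | None

    def __post_init__(self) -> None:
        if self.auc_0_t < 0 or self.cmax < 0 or self.tmax_h < 0:
            raise ValueError("NCA parameters must be non-negative")
        if self.auc_0_inf is not None and self.auc_0_inf < self.auc_0_t - 1e-12:
            raise ValueError("AUC_0-inf cannot be below AUC_0-t")

    def as_dict(self) -> dict[str, float | None]:
        return {"AUC_0_t": self.auc_0_t, "AUC_0_inf": self.auc_0_inf,
                "Cmax": self.cmax, "Tmax": self.tmax_h,
                "lambda_z": self.lambda_z_per_h, "half_life": self.half_life_h}


def _auc_lin_up_log_down(t: np.ndarray, c: np.ndarray) -> float:
    dt = np.diff(t)
    c1, c2 = c[:-1], c[1:]
    lin = (c1 + c2) / 2.0 * dt
    with np.errstate(divide="ignore", invalid="ignore"):
        logdown = (c1 - c2) / np.log(c1 / c2) * dt
    use_log = (c2 < c1) & (c2 > 0)
    return float(np.sum(np.where(use_log, logdown, lin)))


def _terminal_slope(t: np.ndarray, c: np.ndarray,
                    tmax_idx: int) -> tuple[float, int] | None:
    """lambda_z (1/h) by best adjusted-R2 log-linear terminal regression.

    Candidate windows are the last k >= 3 positive-concentration points
    strictly after Tmax.
    """
    after = np.arange(len(t))[(np.arange(len(t)) > tmax_idx) & (c > 0)]
    if len(after) < 3:
        return None
    best = None
    with np.errstate(divide="ignore"):
        logc = np.log(np.maximum(c, 1e-300))
    for k in range(3, len(after) + 1):
        idx = after[-k:]
        x, y = t[idx], logc[idx]
        n = len(x)
        slope, intercept = np.polyfit(x, y, 1)
        yhat = slope * x + intercept
        ss_res = float(np.sum((y - yhat) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        if ss_tot <= 0:
            continue
        r2 = 1.0 - ss_res / ss_tot
        adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
        if slope < 0 and (best is None or adj > best[0]):
            best = (adj, -slope, k)
    if best is None:
        return None
    return best[1], best[2]


def nca(time_h, conc_ng_ml, extrapolate: bool = True) -> PKSummary:
    """Non-compartmental analysis of one profile.

    Requires >= 3 points with strictly increasing times and non-negative
    concentrations. When no terminal slope is estimable the extrapolated
    quantities are reported absent with a warning.
    """
    t = np.asarray(time_h, dtype=float)
    c = np.asarray(conc_ng_ml, dtype=float)
    if len(t) < 3:
        raise ValueError("NCA needs at least 3 points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if np.any(c < 0):
        raise ValueError("concentrations must be non-negative")

    auc_t = _auc_lin_up_log_down(t, c)
    tmax_idx = int(np.argmax(c))
    cmax = float(c[tmax_idx])
    tmax = float(t[tmax_idx])

    if cmax == 0.0:
        return PKSummary(0.0, 0.0, 0.0, tmax, None, None)

    lam = _terminal_slope(t, c, tmax_idx) if extrapolate else None
    if lam is None:
        if extrapolate:
            warnings.warn("no estimable terminal slope; AUC_0-inf reported absent",
                          stacklevel=2)
        return PKSummary(auc_t, None, cmax, tmax, None, None)
    lambda_z, _ = lam
    c_last = float(c[c > 0][-1])
    return PKSummary(auc_0_t=auc_t, auc_0_inf=auc_t + c_last / lambda_z,
                     cmax=cmax, tmax_h=tmax, lambda_z_per_h=lambda_z,
                     half_life_h=math.log(2.0) / lambda_z)


# ---------------------------------------------------------------------------
# fold errors

def mfe(pred: float, obs: float) -> float:
    """Fold error predicted/observed (both must be positive)."""
    if pred <= 0 or obs <= 0:
        raise ValueError("fold errors need positive predicted and observed values")
    return pred / obs


def gmfe(pairs) -> float:
    """Geometric mean fold error: 10**(mean |log10(pred/obs)|); >= 1."""
    ratios = [mfe(p, o) for p, o in pairs]
    if not ratios:
        raise ValueError("gmfe needs at least one pair")
    return 10.0 ** float(np.mean(np.abs(np.log10(ratios))))


def fold_fraction(pairs, fold: float) -> float:
    """Share of pairs whose ratio lies within [1/fold, fold]."""
    if fold < 1:
        raise ValueError("fold must be >= 1")
    ratios = [mfe(p, o) for p, o in pairs]
    ok = [r for r in ratios if max(r, 1.0 / r) <= fold + 1e-12]
    return len(ok) / len(ratios)


@dataclass(frozen=True)
class FoldErrorReport:
    """Per-parameter fold-error summary with the 0.5-2-fold pass rule."""

    per_parameter_mfe: dict[str, list[float]]
    mean_mfe: dict[str, float]
    gmfe_values: dict[str, float]
    fold_fractions: dict[float, float]     # pooled over all parameters
    passed: bool
    failing_parameters: tuple[str, ...] = field(default_factory=tuple)

    def to_text(self) -> str:
        lines = [f"{'parameter':<14}{'mean MFE':>10}{'GMFE':>8}  pass",
                 "-" * 40]
        for k in self.mean_mfe:
            ok = "yes" if k not in self.failing_parameters else "NO"
            lines.append(f"{k:<14}{self.mean_mfe[k]:>10.3f}"
                         f"{self.gmfe_values[k]:>8.3f}  {ok}")
        ff = "  ".join(f"<={f:g}x: {v * 100:.1f}%"
                       for f, v in self.fold_fractions.items())
        lines.append(f"pooled fold fractions: {ff}")
        lines.append(f"overall: {'PASS' if self.passed else 'FAIL'} "
                     "(0.5- to 2-fold rule)")
        return "\n".join(lines)


def evaluate_model(predicted: dict[str, float] | pd.DataFrame,
                   observed: dict[str, float] | pd.DataFrame,
                   folds: tuple[float, ...] = (1.25, 1.5, 2.0)) -> FoldErrorReport:
    """Fold-error comparison of matched predicted/observed PK parameters.

    Inputs are either flat ``{parameter: value}`` mappings or data frames
    with columns (study_id, parameter, value); keys must match exactly. The
    report passes when, for every parameter, mean MFE and GMFE both lie in
    [0.5, 2].
    """
    pred_pairs = _to_pairs(predicted)
    obs_pairs = _to_pairs(observed)
    if set(pred_pairs) != set(obs_pairs):
        missing = sorted(set(pred_pairs) ^ set(obs_pairs))
        raise KeyError(f"mismatched predicted/observed keys: {missing}")

    per_param: dict[str, list[float]] = {}
    for key in pred_pairs:
        param = key[-1]
        per_param.setdefault(param, []).append(
            mfe(pred_pairs[key], obs_pairs[key]))
    mean_mfe = {k: float(np.mean(v)) for k, v in per_param.items()}
    gmfes = {k: 10.0 ** float(np.mean(np.abs(np.log10(v))))
             for k, v in per_param.items()}
    failing = tuple(sorted(
        k for k in per_param
        if not (0.5 <= mean_mfe[k] <= 2.0 and gmfes[k] <= 2.0)))
    pooled = [(pred_pairs[k], obs_pairs[k]) for k in pred_pairs]
    fractions = {f: fold_fraction(pooled, f) for f in folds}
    return FoldErrorReport(per_parameter_mfe=per_param, mean_mfe=mean_mfe,
                           gmfe_values=gmfes, fold_fractions=fractions,
                           passed=not failing, failing_parameters=failing)


def _to_pairs(values) -> dict[tuple, float]:
    if isinstance(values, pd.DataFrame):
        req = {"parameter", "value"}
        if not req <= set(values.columns):
            raise ValueError("data frame needs 'parameter' and 'value' columns")
        sid = values["study_id"] if "study_id" in values.columns \
            else pd.Series(["-"] * len(values))
        return {(s, p): float(v) for s, p, v in
                zip(sid, values["parameter"], values["value"])}
    return {("-", k): float(v) for k, v in values.items()}


# ---------------------------------------------------------------------------
# observed-data files

def read_observed(path) -> pd.DataFrame:
    """Read a delimited observed concentration-time table.

    Columns: study_id, analyte, time_h, conc_ng_per_ml [, n_subjects].
    """
    df = pd.read_csv(path)
    missing = [c for c in OBSERVED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"observed-data file missing columns {missing}")
    return df


def write_observed(df: pd.DataFrame, path) -> None:
    missing = [c for c in OBSERVED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"observed-data frame missing columns {missing}")
    df.to_csv(path, index=False)
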