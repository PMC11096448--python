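"""Access to packaged YAML data files."""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import yaml


@lru_cache(maxsize=None)
def load_packaged_yaml(relpath: str) -> dict:
    """Load (and cache) a YAML file shipped under ``codeine_pbpk/data``."""
    root = resources.files("codeine_pbpk") / "data"
    with (root / relpath).open("r", encoding="utf-8") as fh:
        return yaml.safe_load(fh)
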