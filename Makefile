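.PHONY: test reproduce-table3 acceptance

test:
	python -m pytest -q tests

# The four phenotype-specific single-dose scenarios (EM 30 mg, IM 80 mg,
# PM 1500 mg, UM 20 mg) in the Asian reference individual.
reproduce-table3:
	codeine-pbpk simulate --config examples/em_30mg_single.yaml --out-dir out/table3/em
	codeine-pbpk simulate --config examples/im_80mg_single.yaml --out-dir out/table3/im
	codeine-pbpk simulate --config examples/pm_1500mg_single.yaml --out-dir out/table3/pm
	codeine-pbpk simulate --config examples/um_20mg_single.yaml --out-dir out/table3/um

acceptance:
	python scripts/acceptance.py --seed 1 --out results/acceptance.json
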