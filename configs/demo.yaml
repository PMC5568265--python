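# Bundled fully-synthetic demo for `hybridhic run-all --config configs/demo.yaml`.
# Every protocol-level constant keeps its published default (ice_eps 1e-4,
# 20-kb/5-kb resolutions, 100-kb decay windows, 50-kb methylation bins,
# 100-bp ChIP windows, >0.5 marking fraction, FDR 0.05, FISH threshold 25
# and 0.22-um slices); only the two required free choices appear here.
seed: 20170822
min_abs_log2fc: 1.0
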