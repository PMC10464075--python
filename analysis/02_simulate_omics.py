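#!/usr/bin/env python
"""Generate the synthetic heat-stress study inputs.

Emulates the sequencing design: 3 control vs 3 high-temperature pooled
samples, ~20k CG and ~1.8k CWG methylation sites at mean depth ~10 over
2,000 gene models, matched RNA-seq counts, planted promoter-methylation
and expression effects (|log2FC| = 2) including 8 positively and 7
negatively methylation-coupled genes, a toy term map, and qPCR Ct rows.

Writes the input bundle plus the ground-truth manifest to
results/synthetic/.
"""

from pathlib import Path

from thermomethyl.simulate import SimulationConfig, simulate_all

OUT = Path(__file__).resolve().parent.parent / "results" / "synthetic"

cfg = SimulationConfig(seed=20230828)
paths = simulate_all(cfg, OUT)
for name, p in paths.items():
    print(f"{name:>12}: {p} ({p.stat().st_size // 1024} kB)")
print(
    f"\n{cfg.n_cg_sites} CG + {cfg.n_cwg_sites} CWG sites, "
    f"{cfg.n_genes} genes, {cfg.n_samples_per_group}/group, "
    f"depth mean {cfg.depth_mean}, NB dispersion {cfg.nb_dispersion}"
)
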