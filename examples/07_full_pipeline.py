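"""End-to-end run: simulate two barcoded libraries, process, quantify, report.

The report shows collapsed counts tracking the simulated ground truth
better than raw read counts, and dispersing less between replicates.
"""

from srnakit import RunConfig, run_pipeline

config = RunConfig(seed=42, n_reads=5000, n_species=120, seq_error_rate=0.0)
report = run_pipeline(config)

for sample, info in report["samples"].items():
    print(f"{sample}: {info['reads']} reads, status {info['status_counts']}, "
          f"dimers {info['dimer_fraction']:.3f}")

corr = report["truth_correlation"]
print(f"\nSpearman correlation with ground-truth molecule counts:")
print(f"  raw reads       {corr['raw']:.3f}")
print(f"  collapsed (UMI) {corr['collapsed']:.3f}")

disp = report["dispersion"]
print(f"mean replicate dispersion:")
print(f"  raw       {disp['raw']['mean_dispersion']:.2f}")
print(f"  collapsed {disp['collapsed']['mean_dispersion']:.2f}")
# UMI collapsing removes amplification noise: higher truth correlation,
# lower between-replicate dispersion.
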