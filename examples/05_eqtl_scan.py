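"""Cis-eQTL scan on a simulated genotype-expression panel.

Simulates a 447-sample panel over the NUDT15 region (chr13, hg19) with one
causal variant (beta = -0.5 per variant allele), filters variants carried
by fewer than three individuals, and regresses expression on dosage for
every variant.  The causal variant should top the p-value ranking with a
slope estimate near the planted effect.
"""

from thiometa import filter_snps, scan
from thiometa.simulate import EqtlSimConfig, simulate_eqtl_panel

panel, expression = simulate_eqtl_panel(EqtlSimConfig(seed=42))
panel = filter_snps(panel, min_carriers=3)
result = scan(panel, expression)

print(f"{panel.n_snps} variants tested in {panel.n_samples} samples")
print(result.head(5)[["snp_id", "pos", "n", "beta", "se", "p"]].to_string(index=False))
top = result.iloc[0]
print(f"top hit: {top['snp_id']} at chr{top['chrom']}:{top['pos']}, "
      f"beta {top['beta']:.3f}, p = {top['p']:.2e}")
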