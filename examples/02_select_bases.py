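"""Filter the learned bases down to those informative about cell identity.

Two data-driven screens: bases whose scores track sequencing depth
(|Pearson r| >= 0.7 with per-cell total log counts) are removed, and only
bases whose score distribution across cells is multimodal (excess-mass
bootstrap test, BH-controlled FDR 1%) are kept.
"""
import projnmf as pj

raw, truth = pj.simulate_counts(seed=1)
X = pj.log_transform(raw)
W, S, _ = pj.fit_pnmf(X, K=20)

W_S, reports = pj.select_bases(W, S, X, B=500, seed=3)
table = pj.report_frame(reports)
print(table[["basis_label", "libsize_correlation", "multimodality_pvalue",
             "adjusted_pvalue", "retained"]].round(3).to_string(index=False))
print(f"\nselected {W_S.n_bases} of {W.n_bases} bases")

# The basis with the highest depth correlation is dominated by the
# planted housekeeping genes -- exactly the unwanted variation the
# screen exists to remove:
depth = max(reports, key=lambda r: abs(r.libsize_correlation))
hk = set(truth.housekeeping_genes)
share = len(hk.intersection(depth.top_genes)) / len(depth.top_genes)
print(f"most depth-correlated basis: {depth.basis_label} "
      f"(r = {depth.libsize_correlation:.2f}, "
      f"{100 * share:.0f}% housekeeping in its top genes)")
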