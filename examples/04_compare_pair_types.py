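"""The headline comparison: orthologs versus closest non-orthologs.

Simulates 200 families with ancestral introns and deeper outparalogs, runs
the whole analysis, and prints the per-type mean IPC, the Mann-Whitney-
Wilcoxon p-values, and the identity-binned log2 ratios that control for the
orthologs' higher sequence identity.
"""

from ipcon import analyze_dataset
from ipcon.synthetic_data import headline_params, simulate_dataset

ds = simulate_dataset(headline_params(200), seed=11)
report = analyze_dataset(ds, cluster_source="similarity",
                         with_annotations=False).report

print("mean IPC per pair type:")
for t, v in report["mean_ipc"].items():
    print(f"  {t:6s} {v:.3f}  (n={report['n_values'][t]})")
print("MWW p (o-o vs o-cno):", f"{report['mww_p']['o-o_vs_o-cno']:.3g}")
print("MWW p (i-i vs i-cni):", f"{report['mww_p']['i-i_vs_i-cni']:.3g}")

binning = report["binning"]["o-o_vs_o-cno"]
print("\nidentity-binned log2(mean IPC o-o / mean IPC o-cno):")
for i, ratio in enumerate(binning["log2_ratio"]):
    shown = "undef" if ratio is None else f"{ratio:+.2f}"
    print(f"  bin {i}: {shown}  (n_oo={binning['counts_type1'][i]}, "
          f"n_ocno={binning['counts_type2'][i]})")
# Positive log2 ratios across (nearly) all identity bins show that orthologs
# keep more intron positions than equally similar non-orthologs - sequence
# identity alone does not explain the difference.
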