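"""Pick one representative descriptor per cluster by correlation strength.

Uses the packaged cluster labels (500 training steps) and the published
descriptor-experiment correlation magnitudes for both DFT basis sets.
Singleton groups pass through; each multi-member group contributes its
highest-|r| member, so the chosen set keeps the information content of all
twelve descriptors with no redundancy.
"""

from sofmrbf import CANONICAL_DESCRIPTORS, CorrelationReport, Partition, load_table2_fixture, select_representatives

R = {
    "6-31G(d)": (0.64, 0.46, 0.49, 0.02, 0.12, 0.18, 0.28, 0.43, 0.51, 0.17, 0.05, 0.27),
    "STO-3G": (0.35, 0.39, 0.43, 0.05, 0.12, 0.03, 0.31, 0.40, 0.48, 0.06, 0.05, 0.34),
}

names = list(CANONICAL_DESCRIPTORS)
records = {(r.basis, r.training_steps): r for r in load_table2_fixture()}
for basis in ("6-31G(d)", "STO-3G"):
    partition = Partition.from_labels(records[(basis, 500)].label_vector(), names)
    report = CorrelationReport(dict(zip(names, R[basis])))
    result = select_representatives(partition, report)
    print(f"{basis}: {len(partition)} groups -> {len(result.chosen)} descriptors")
    print("  selected:", ", ".join(result.chosen))
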