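"""Exact count-based differential expression between two sRNA libraries.

Counts are normalized to reads per million (RPM); the p-value is the exact
two-tail Audic-Claverie-type comparison given each library's total depth.
"""

from plantmir import ac_pvalue, build_records, call_de, ddct

counts = [
    ("miR-drought-up", 120, 510),   # ~4-fold induction
    ("miR-flat", 300, 295),         # unchanged
    ("miR-low", 4, 9),              # too few reads to call
]
records = build_records(counts, n1=1_000_000, n2=1_000_000)
table = call_de(records, min_rpm=1.0, fold=2.0, alpha=0.01)
print(table[["name", "rpm_control", "rpm_drought", "log2_ratio", "p_value", "call"]]
      .to_string(index=False))

print(f"\np(x=0, y=0) = {ac_pvalue(0, 0, 10**6, 10**6)}   (one shared formula anchor)")

rec = ddct(ct_target_treat=20, ct_ref_treat=15, ct_target_ctrl=22, ct_ref_ctrl=15)
print(f"RT-qPCR 2^-ddCt: ddCt = {rec.ddct} -> relative expression {rec.relative_expression}x")
# A call requires >= 2-fold change at p <= 0.01 after discarding tags below
# 1 RPM in both libraries; the qPCR block converts Ct values to fold change.
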