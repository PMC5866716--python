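"""Recompute habitat-change percentages from published transition matrices.

Loads the shipped 2003→2016 ensemble transition matrices for a 984 ha
protected coastal wetland and derives each class's percent change from the
matrix marginals — the same computation the pipeline applies to its own
maps.
"""

from wetlandchange import load_published_transitions, percent_change

for rule, tm in load_published_transitions().items():
    print(f"{rule} ({tm.date_from} -> {tm.date_to}), "
          f"analyzed area {tm.total_area:.2f} ha")
    rows, cols = tm.row_sums(), tm.col_sums()
    for cid in tm.class_ids:
        pct = percent_change(tm)[cid]
        shown = "   n/a (absent in 2003)" if pct != pct else f"{pct:+6.1f}%"
        print(f"  {tm.class_names[cid]:<14s} {rows[cid]:7.2f} -> "
              f"{cols[cid]:7.2f} ha  {shown}")
    print()
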