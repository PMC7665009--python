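"""Detect heterochronies on the combined (all-landmark) analysis.

Each reported event says a species is late (it still lacks characters
the others already show at that percentage of development) or advanced
(it alone already shows them). The set-based modes read the matrix
directly; the tree mode reads ACCTRAN character gains off the strict
consensus of all most parsimonious trees.
"""

from ontochron import TimeFrame, analyze_frame, load_fixture_table1

table1 = load_fixture_table1()
report = analyze_frame(table1, TimeFrame((5, 10, 20, 25, 50, 75)))

print(
    f"frame {report.frame.name()}: length {report.best_length}, "
    f"{report.n_trees} MP trees, CI {report.reported_ci:.2f}, "
    f"RI {report.reported_ri:.2f}\n"
)
names = {c.index: c.name for c in table1.characters}
for e in report.events:
    if e.mode != "tree":
        continue
    chars = ", ".join(f"{c} ({names[c]})" for c in sorted(e.characters))
    print(f"{e.species} is {e.direction} at {e.landmark:g}%: {chars}")
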