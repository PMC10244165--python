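"""Exact contingency statistics for the remission-rate comparisons.

Two 2x2 comparisons of complete-remission (CR/CRp) counts: WT1-mutated vs
WT1-wild-type among TD carriers (4/10 vs 10/11), and TD vs wild-type among
WT1-mutated patients (4/10 vs 38/48).  The two-sided Fisher exact test uses
exact integer arithmetic; q-values apply Benjamini-Hochberg correction.
"""

from ubtftd import ContingencyTable, benjamini_hochberg, fisher_exact_two_sided, odds_ratio

tables = {
    "WT1-mut vs WT1-wt within TD carriers": ContingencyTable(4, 6, 10, 1),
    "TD vs wild-type within WT1-mutated":   ContingencyTable(4, 6, 38, 10),
}
ps = {name: fisher_exact_two_sided(t) for name, t in tables.items()}
qs = benjamini_hochberg(list(ps.values()))

for (name, p), q in zip(ps.items(), qs):
    t = tables[name]
    print(f"{name}:")
    print(f"  table [[{t.a},{t.b}],[{t.c},{t.d}]]  p = {p:.3f}  q = {q:.3f}  OR = {odds_ratio(t):.2f}")
# Both p-values land below 0.05: lower remission rates track WT1 mutation
# within TD carriers and TD status within WT1-mutated patients.
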