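"""Term and set similarity on a hand-checkable seven-term ontology.

Builds the tiny DAG used throughout the test-suite, computes corpus-based
information content and prints a few Lin and best-match-average values.
"""

from subgofa import OntologyDAG, compute_ic, lin_similarity, mica, set_similarity

parents = {
    "r": set(), "a": {"r"}, "b": {"r"},
    "c": {"a"}, "d": {"a"}, "e": {"b"}, "f": {"c", "d"},
}
dag = OntologyDAG(
    terms=set(parents),
    names={t: t for t in parents},
    namespace={t: "biological_process" for t in parents},
    parents=parents,
)
corpus = {"g1": {"c"}, "g2": {"d"}, "g3": {"e"}, "g4": {"f"}, "g5": {"a"}}
ic = compute_ic(dag, corpus)

print("IC values (nats): rarer terms carry more information")
for t in sorted(dag.terms):
    print(f"  IC({t}) = {ic[t]:.4f}")

print(f"\nmica(c, d) = {mica('c', 'd', dag, ic)}   # most informative shared ancestor")
print(f"lin(c, d)  = {lin_similarity('c', 'd', dag, ic):.4f}")
print(f"lin(c, e)  = {lin_similarity('c', 'e', dag, ic):.4f}   # only the root is shared")

s = set_similarity({"c", "f"}, {"d"}, dag, ic)
print(f"\nBMA({{c,f}}, {{d}}) = {s:.4f}")
print("Restricting the ancestor search to sub-GO(a) can only use ancestors")
print("inside that branch:")
s_restricted = set_similarity({"c", "f"}, {"d"}, dag, ic, restrict=dag.subgo("a"))
print(f"BMA restricted to sub-GO(a) = {s_restricted:.4f}")
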