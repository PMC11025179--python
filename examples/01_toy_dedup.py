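"""The worked toy example: why wildcard dedup is a maximal-independent-set choice.

Three reads — TAC, TNC, TGC — form a path in the equivalence graph: TNC
matches both neighbours through its 'N', but TAC and TGC genuinely differ.
A deduplicated set is a maximal independent set of that graph, and there are
two: the unambiguous tips {TAC, TGC}, or the ambiguous center {TNC}.
"""

from wildtrie import SeqRecord, dedup_pairwise, dedup_trie

reads = [SeqRecord(f"r{i}", s, input_rank=i) for i, s in enumerate(["TAC", "TNC", "TGC"])]

for fn in (dedup_trie, dedup_pairwise):
    result = fn(reads)
    print(f"{result.method:>8}: representatives = {[r.seq for r in result.representatives]}")

# Default processing sorts by ascending 'N' count, so the clean tips are
# admitted first and TNC collapses onto TAC.  Forcing the ambiguous read to
# the front instead yields the other (smaller) MIS:
forced = dedup_trie(reads[1:2] + reads[0:1] + reads[2:3], presorted=True)
print(f"forced TNC-first: representatives = {[r.seq for r in forced.representatives]}")
print("-> both answers are valid deduplications; the ascending-N order is the")
print("   convention that keeps the least-ambiguous reads as representatives.")
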