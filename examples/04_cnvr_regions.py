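"""Merge per-animal CNV calls into CNV regions and summarise them.

Overlapping calls from different animals aggregate into one region (union
span); a region is Loss if every supporting call is a deletion, Gain if
every call is a duplication, Both otherwise.
"""

from ovinecnv import cnvr
from ovinecnv.hmm import CnvCall


def call(sample, chrom, start, end, cn):
    state = {0: "CN0", 1: "CN1", 3: "CN3", 4: "CN4"}[cn]
    return CnvCall(sample, chrom, start, end, state, cn, 5, 10.0)


calls = [
    call("arab_01", "1", 1_000_000, 1_250_000, 1),
    call("arab_02", "1", 1_200_000, 1_400_000, 1),   # overlaps -> same region
    call("baluchi_01", "1", 1_350_000, 1_500_000, 3),  # duplication joins -> Both
    call("arab_03", "2", 5_000_000, 5_300_000, 3),
    call("gadik_01", "2", 9_000_000, 9_080_000, 0),
]
breed_of = {s: s.split("_")[0] for s in ("arab_01", "arab_02", "arab_03", "baluchi_01", "gadik_01")}

regions = cnvr.merge_calls(calls, breed_of)
for r in regions:
    print(f"chr{r.chromosome}:{r.start_bp}-{r.end_bp}  {r.status:4s} "
          f"({len(r.samples)} animals: {','.join(r.breeds)})")

summary = cnvr.summarize(events=regions, n_samples=5)
print(f"\n{summary.n_events} regions, total {summary.total_length_kb:.0f} kb, "
      f"mean {summary.mean_length_kb:.0f} kb, median {summary.median_length_kb:.0f} kb")
print(f"size classes [20,100)/[100,500]/>500 kb: {summary.size_class_counts} "
      f"= {summary.size_class_percent} %")
print(f"genome proportion per animal: {summary.genome_proportion_percent:.4f} %")

per_breed = cnvr.merge_calls(calls, breed_of, scope="per-breed")
venn = cnvr.venn_counts(per_breed)
print("\nbreed sharing (Venn partition):")
for combo, n in sorted(venn.items(), key=lambda kv: sorted(kv[0])):
    print(f"  {'+'.join(sorted(combo)):24s} {n}")
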