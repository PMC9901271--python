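"""Two-hop pruning partition: which animals can leave the genomic run.

Animals whose equations exchange no genomic information within two hops
(not parent/progeny/mate of a genotyped animal, nor of such a neighbour)
are class 0: they can be dropped from the single-step system and
evaluated by plain pedigree BLUP on the side.
"""

from ssram import load_paper_example, prune_partition, prune_pedigree

ex = load_paper_example()
part = prune_partition(ex.ped, ex.genotyped)
for cls in (2, 3, 4, 0):
    members = sorted(a for a, c in part.items() if c == cls)
    label = {2: "genotyped", 3: "one hop from genotyped",
             4: "two hops", 0: "prunable"}[cls]
    print(f"class {cls} ({label}): {members}")

pruned, removed = prune_pedigree(ex.ped, part)
print(f"\npruned pedigree keeps {pruned.n} of {ex.ped.n} animals; "
      f"removed {removed}")
print("Animal 3 only touches the genotyped animals through grandchildren,")
print("so its evaluation is (to numerical accuracy) unaffected by genomics.")
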