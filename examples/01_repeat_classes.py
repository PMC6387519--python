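"""Enumerate microsatellite repeat classes and their GC categories.

Every 1-6 nt DNA motif that is not itself a tandem repetition of a shorter
word is a primitive motif; motifs that are cyclic rotations of each other or
of each other's reverse complement describe the same repeat and collapse
into one canonical class.
"""

from collections import Counter

from ssrscape import canonical_class, class_table, enumerate_classes, enumerate_primitive_motifs

motifs = enumerate_primitive_motifs(6)
classes = enumerate_classes(6)
print(f"primitive 1-6 nt motifs : {len(motifs)}")
print(f"canonical repeat classes: {len(classes)}")

per_k = Counter(c.k for c in classes)
print("classes per motif size  :", dict(sorted(per_k.items())))

for motif in ("TTC", "GATA", "CTCGAG"):
    print(f"class of {motif!s:>6} -> {canonical_class(motif)}")

gc = Counter(c.gc_category for c in classes)
print("classes per GC category :", {k: gc[k] for k in ("LE25", "GC26_49", "GC50", "GC51_74", "GE75")})
print(class_table(2).to_string(index=False))
# The counts say: 5356 motifs collapse ~10x into 501 classes; the GC category
# of a class is computed on the 12 bp string made by repeating its motif.
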