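"""Classify a focal species' orthology relationships from a gene tree.

A single liverwort gene sitting sister (through speciation nodes) to a
duplicated angiosperm clade is a "proto-ortholog": one focal gene
corresponding to several reference genes born after the lineages split.
"""

from amtoolkit import classify_family, label_duplications, parse_gene_tree

panel = ["Mpaleacea", "Mpolymorpha", "Medicago", "Oryza"]

for name, newick in [
    ("one-to-one", "((Mpaleacea|f1,Mpolymorpha|p1),(Oryza|o1,Medicago|m1));"),
    ("proto-ortholog", "(Mpaleacea|f1,(Medicago|m1,(Medicago|m2,Oryza|o1)));"),
    ("absent", "(Mpolymorpha|p1,(Oryza|o1,Medicago|m1));"),
]:
    tree = label_duplications(parse_gene_tree(newick))
    rec = classify_family(
        tree, name, focal_species="Mpaleacea",
        genus_partner_species="Mpolymorpha",
        reference_clades={"angiosperms": ["Medicago", "Oryza"]},
        panel_species=panel,
    )
    print(f"{name:15s} status={rec.focal_status:15s} "
          f"one_to_one={rec.one_to_one} proto={rec.proto_ortholog} "
          f"reference_orthologs={rec.reference_ortholog_gene_ids}")

print()
print("Each focal gene's ortholog set is every reference gene whose last "
      "common ancestor with it is a speciation node (species-overlap "
      "duplication labelling); copy numbers per reference species decide "
      "the class.")
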