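"""Detect a shared ancestral numt (synaponumt) and bound its age.

Plants one insertion in the common ancestor of the two most recently
diverged taxa of a simulated tree.  Both descendants inherit the numt,
so the bootstrapped NJ tree recovers a two-species numt-only clade; a
fossil calibration for that species pair then bounds the insertion age.
The bundled calibration table does the same for the published
orthopteran clades.
"""

from numtscope import SimulationConfig, simulate
from numtscope.classify import (
    CalibrationRow, FossilCalibration, date_insertion, detect_synaponumts,
)
from numtscope.datasets import load_fossil_calibrations
from numtscope.pipeline import infer_tree
from numtscope.simulate import simulate_species_tree

seed = 3
tree = simulate_species_tree(6, 100.0, seed)
cherry = min((x for x in tree.preorder_node_iter() if not x.is_leaf()),
             key=lambda x: x.age)
species = sorted(leaf.taxon.label for leaf in cherry.leaf_iter())
age = cherry.age + 10.0

config = SimulationConfig(
    seed=seed, n_taxa=6, root_age=100.0, insertion_rate=0.0, indel_rate=0.0,
    duplication_rate=0.0, retention_prob=1.0, clones_per_sample=0,
    planted_insertions=((age, species[0]),),
)
survey = simulate(config)
inferred = infer_tree(survey.ortholog_records() + survey.numt_records(),
                      bootstrap=200, seed=seed)

calib = FossilCalibration(rows=[
    CalibrationRow(frozenset(species), "simulated fossil group",
                   round(cherry.age, 1), round(age + 5, 1)),
])
print(f"insertion planted {age:.1f} MY ago, ancestral to {species}")
for clade in detect_synaponumts(inferred, min_species=2):
    dated = date_insertion(clade, calib)
    print(f"  synaponumt clade {clade.mrca_label}, "
          f"members {clade.member_clone_ids}, support {clade.support}")
    print(f"  fossil-bounded insertion age: "
          f"{dated.age_min_my}-{dated.age_max_my} MY")

print("\npublished orthopteran clades (bundled calibrations):")
published = load_fossil_calibrations()
for group in ({"Eumastacidae", "Pyrgacrididae"},
              {"Lentulidae", "Pamphagodidae", "Pneumoridae",
               "Prophalangopsidae"}):
    dated = date_insertion(group, published)
    print(f"  {'+'.join(sorted(group))}: "
          f"{dated.age_min_my}-{dated.age_max_my} MYA")
# A multi-species numt-only clade implies insertion in the MRCA, so the
# oldest fossil for that group is a maximum bound on the insertion date.
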