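"""Design FISH oligo probes for the non-TE families of a synthetic assembly.

Runs discovery on the reference scenario's primary assembly, annotates
against the synthetic repeat library, then designs one 18-27 nt oligo per
probe-worthy family and prints its QC metrics.
"""
from satfam import detect_all, remove_redundant, three_assembly_scenario
from satfam.families import (annotate_library, assign_names, cluster_families,
                             score_pairs)
from satfam.probes import design_probe

assemblies, truth, library, _, _ = three_assembly_scenario(seed=42)
catalog = remove_redundant(detect_all(assemblies["A1"]), assembly_id="A1")
families = assign_names(cluster_families(catalog, score_pairs(catalog)),
                        species_prefix="", assembly_id="A1")
for fam in families:
    annotate_library(fam, catalog, library)

for fam in families:
    if fam.is_te:
        print(f"{fam.name}: skipped (similar to {fam.te_similarity}, a TE)")
        continue
    probe = design_probe(fam, catalog, families)
    print(f"{fam.name}: {probe.sequence}  len={len(probe.sequence)} "
          f"GC={probe.gc_percent:.1f}% homopolymer<={probe.max_homopolymer} "
          f"self-comp={probe.self_complementarity} "
          f"array coverage={100 * probe.array_coverage:.0f}%")
# Each oligo is a window of its family's consensus monomer that passes the
# GC / homopolymer / self-annealing / cross-family gates and is found (at
# <= 2 mismatches) in every array of the family.
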