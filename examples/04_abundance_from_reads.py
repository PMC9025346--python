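"""Estimate a family's genome abundance from raw reads.

Implants one 50 bp family at a known genomic fraction, simulates 20x reads,
and counts the reads whose 21-mers place them in the family's arrays.
"""
import numpy as np

from satfam import ImplantSpec, TRFamily, estimate_abundance, make_assemblies, make_reads

specs = [ImplantSpec(name="sat50", monomer_length=50, substitution_rate=0.01,
                     copies=(20, 20), n_arrays=4)]
assemblies, truth = make_assemblies(specs, 1, [80_000], 0.45, seed=7)
reads, _ = make_reads(assemblies["A1"], read_length=100, coverage=20.0,
                      error_rate=0.005, seed=7, truth=truth, assembly_id="A1")

contigs = {r.id: r.sequence for r in assemblies["A1"]}
array_seqs = [contigs[c][s:e] for c, s, e in truth.intervals["sat50"]["A1"]]
family = TRFamily(family_id=0, name="sat50", members=[], min_monomer=50,
                  representative=truth.monomers["sat50"], max_array_len=1000,
                  gc_percent=50.0)
est = estimate_abundance(family, array_seqs, reads, min_kmer_fraction=0.5, k=21)

frac = truth.fractions["sat50"]["A1"]
sigma = np.sqrt(frac * (1 - frac) / est.reads_total)
print(f"implanted fraction: {100 * frac:.3f}% of the genome")
print(f"estimate: {est.reads_aligned}/{est.reads_total} reads aligned "
      f"= {est.percent:.3f}%")
print(f"|error| = {abs(est.percent - 100 * frac):.3f} pp "
      f"({abs(est.percent / 100 - frac) / sigma:.1f} binomial sigma)")
# The k-mer containment estimate tracks the implanted fraction to within a
# few binomial standard deviations of the read-sampling noise.
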