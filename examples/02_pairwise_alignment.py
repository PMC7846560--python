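"""Pairwise structural alignment of two CA traces.

Aligns two synthetic structures that differ by a 15-residue insertion and
an arbitrary rigid motion, and prints the aligned length, RMSD, TM-score
and structure-based sequence identity.  The TM-score is normalised by the
reference length: 1.0 means identical structures, ~0.2 is the random-pair
baseline, and > 0.5 indicates a shared fold.
"""

from pvrscan import align_pair, generate_ensemble
from pvrscan.synthetic import PlantedRegion, SyntheticEnsembleSpec

spec = SyntheticEnsembleSpec(
    n_structures=2,
    core_blocks=(60, 60),
    planted_regions=(PlantedRegion(0, (0, 15)),),
    noise_sigma=0.3,
    seed=7,
)
a, b = generate_ensemble(spec).structures

al = align_pair(a, b)
print(f"{al.a_id} vs {al.b_id}")
print(f"  aligned residues : {al.n_aligned} (of {a.n_polymer_residues} / {b.n_polymer_residues})")
print(f"  RMSD             : {al.rmsd:.3f} A over aligned CA pairs")
print(f"  TM-score         : {al.tm_score:.4f} (normalised by reference length)")
print(f"  seq identity     : {al.seq_identity:.1f} %")
# The 15 inserted residues of the target stay unaligned; the conserved core
# aligns end to end despite the 0.3 A coordinate noise.
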