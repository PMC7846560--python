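"""Metal coordination spheres and interface geometry.

Constructs a micro-model of a zinc site and a two-chain contact, then runs
the coordination-sphere detector (N/O/S atoms within 3.0 A of the metal,
inclusive) and the buried-interface-area / hydrogen-bond analyses.
"""

import numpy as np

from pvrscan import count_interface_hbonds, find_metal_sites, interface_area
from pvrscan.structure_io import Atom, Chain, MetalAtom, Residue, ResidueRef, Structure


def residue(sid, cid, num, name, atoms):
    return Residue(
        ref=ResidueRef(sid, cid, num),
        name=name,
        atoms=[Atom(name=n, element=e, pos=p) for n, e, p in atoms],
    )


site = Structure(
    id="demo",
    chains=[
        Chain(
            chain_id="A",
            residues=[
                residue("demo", "A", 54, "HIS", [("NE2", "N", (2.1, 0.0, 0.0))]),
                residue("demo", "A", 58, "ASP", [("OD1", "O", (0.0, 2.2, 0.0))]),
                residue("demo", "A", 118, "HIS", [("ND1", "N", (0.0, 0.0, 2.3))]),
            ],
        )
    ],
    metals=[MetalAtom(element="Zn", name="ZN", chain_id="A", seq_id=301, pos=(0.0, 0.0, 0.0))],
)

for cs in find_metal_sites(site, cutoff=3.0):
    print(f"metal {cs.metal.label} coordinated by:")
    for lig in cs.ligands:
        print(f"  {lig.resname}{lig.ref.seq_id}/{lig.atom}  {lig.distance:.2f} A")

# two small chains in contact
rng = np.random.default_rng(0)
chains = []
for cid, offset in (("A", 0.0), ("B", 5.5)):
    residues = [
        residue("iface", cid, i + 1, "SER", [("OG", "O", tuple(p))])
        for i, p in enumerate(rng.uniform(0, 6, (8, 3)) + np.array([offset, 0, 0]))
    ]
    chains.append(Chain(chain_id=cid, residues=residues))
iface = Structure(id="iface", chains=chains)

area = interface_area(iface, ("A", "B"))
rep = count_interface_hbonds(iface, ("A", "B"), d_max=3.5)
print(f"\nburied interface area A|B: {area:.1f} A^2 (half the buried SASA)")
print(f"inter-chain hydrogen bonds (heavy-atom <= 3.5 A): {rep.hbond_count}")
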