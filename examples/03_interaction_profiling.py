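"""Geometric profiling of a protein-ligand complex.

Builds a synthetic complex with two hydrogen bonds, one apolar contact and
two aromatic stacks planted at exact geometries, writes it as PDB, reads it
back, and profiles it: close contacts, stacking classification and the
per-complex interaction summary.
"""

import tempfile
from pathlib import Path

from tg2screen.structure import (
    aromatic_interactions, close_contacts, interaction_summary,
    read_complex, write_complex_pdb,
)
from tg2screen.synthetic import ComplexSpec, gen_complex

spec = ComplexSpec(n_hbonds=2, n_apolar=1,
                   stacks=("parallel", "t_shaped"), seed=21)
cx, truth = gen_complex(spec)

with tempfile.TemporaryDirectory() as td:
    pdb = Path(td) / "complex.pdb"
    write_complex_pdb(cx, pdb)
    cx = read_complex(pdb, "LIG")   # same partition after a PDB round trip

print("contacts (protein atom -- ligand atom, distance, class):")
for r in close_contacts(cx)[:8]:
    print(f"  {r.protein_atom.res_name}{r.protein_atom.res_id}/"
          f"{r.protein_atom.name:3s} -- {r.ligand_atom.name:4s} "
          f"{r.distance:5.2f} A  {r.klass}")

print("\naromatic interactions:")
for a in aromatic_interactions(cx):
    print(f"  {a.protein_ring.label} vs {a.ligand_ring.label}: "
          f"d={a.distance:.2f} A, angle={a.angle:.1f} deg, "
          f"offset={a.offset:.2f} A -> {a.klass}")

n_contacts, n_aromatic = interaction_summary(cx)
print(f"\nsummary: {n_contacts} close contacts "
      f"({truth['census_hbonds']} hydrogen bonds planted), "
      f"{n_aromatic} aromatic interactions")
print("\nPolar atom pairs within 3.5 A count as hydrogen bonds, any other "
      "heavy-atom pair within 4.0 A as a close contact; ring pairs within "
      "5.5 A are classified parallel / parallel-displaced / T-shaped from "
      "their interplanar angle and lateral offset. The planted geometry is "
      "recovered exactly, including the incidental ring-carbon contacts a "
      "T-shaped stack produces.")
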