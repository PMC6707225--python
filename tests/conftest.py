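import numpy as np
import pytest

from cskinetics import extract, reference, simulate

# Standard excess-ligand titration design: 8 PPACK concentrations 2.5-70 uM
# against 150 nM protein, the stopped-flow window of the study.
LIGAND_POINTS = (2.5, 5.0, 10.0, 15.0, 25.0, 40.0, 55.0, 70.0)
PROTEIN_UM = 0.15


def atom_line(serial, name, resname, chain, resnum, x, y, z, occ=1.0, altloc=" "):
    return (
        f"ATOM  {serial:5d}  {name:<3s}{altloc}{resname:>3s} {chain}{resnum:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}  0.00           C"
    )


def write_gauge_pdb(path, placements):
    """Synthetic minimal PDB: one Calpha for G193 and G216 per chain.

    ``placements`` maps chain id -> (xyz_193, xyz_216).  Purely artificial
    coordinates for exercising the distance gauge.
    """
    lines = []
    serial = 1
    for chain, (p193, p216) in placements.items():
        lines.append(atom_line(serial, "CA", "GLY", chain, 193, *p193))
        serial += 1
        lines.append(atom_line(serial, "CA", "GLY", chain, 216, *p216))
        serial += 1
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path


_CIF_HEADER = """data_synth
loop_
_atom_site.group_PDB
_atom_site.id
_atom_site.type_symbol
_atom_site.label_atom_id
_atom_site.label_alt_id
_atom_site.label_comp_id
_atom_site.label_asym_id
_atom_site.label_entity_id
_atom_site.label_seq_id
_atom_site.auth_seq_id
_atom_site.auth_asym_id
_atom_site.Cartn_x
_atom_site.Cartn_y
_atom_site.Cartn_z
_atom_site.occupancy
_atom_site.B_iso_or_equiv
_atom_site.pdbx_PDB_model_num
"""


def write_gauge_cif(path, placements):
    """Synthetic mmCIF gauge fixture with full-precision coordinates."""
    lines = []
    serial = 1
    for chain, (p193, p216) in placements.items():
        for num, xyz in ((193, p193), (216, p216)):
            x, y, z = xyz
            lines.append(
                f"ATOM {serial} C CA . GLY {chain} 1 {num} {num} {chain} "
                f"{x:.10f} {y:.10f} {z:.10f} 1.00 0.0 1"
            )
            serial += 1
    path.write_text(_CIF_HEADER + "\n".join(lines) + "\n")
    return path


def simulate_wt_titration(seed=1, noise=0.05, ligands=LIGAND_POINTS):
    rc = reference.CS_VARIANTS["wt"]
    design = simulate.TitrationDesign(ligands, PROTEIN_UM)
    cfg = simulate.TraceConfig(seed=seed, noise_fraction=noise)
    return simulate.simulate_titration(rc, design, cfg)


@pytest.fixture(scope="session")
def wt_dataset():
    """Extracted relaxation dataset of one noisy wild-type titration."""
    traces, truth = simulate_wt_titration(seed=1)
    return extract.extract_titration(traces), truth


@pytest.fixture(scope="session")
def e217a_dataset():
    """Extracted dataset for the lock-and-key mutant E217A."""
    rc = reference.variant_rate_constants("E217A")
    design = simulate.TitrationDesign(LIGAND_POINTS, PROTEIN_UM)
    cfg = simulate.TraceConfig(seed=2, noise_fraction=0.05)
    traces, truth = simulate.simulate_titration(rc, design, cfg)
    return extract.extract_titration(traces), truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
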