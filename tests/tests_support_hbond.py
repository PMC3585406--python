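"""Helper: a constructed (synthetic) threonine→aspartate hydrogen-bond
geometry with the hydroxyl H placed 1.81 Å from the carboxylate oxygen."""

import numpy as np

from mutsmith.structure import Atom, MolecularStructure, Residue


def build_thr_asp_contact() -> MolecularStructure:
    thr = Residue("THR", 178, atoms=[
        Atom("CB", "C", np.array([-1.42, -0.4, 0.0]), 1.7, 0.0),
        Atom("OG1", "O", np.array([0.0, 0.0, 0.0]), 1.52, -0.4),
        Atom("HG1", "H", np.array([0.93, -0.24, 0.0]), 1.10, 0.4),
    ])
    # acceptor placed exactly 1.81 A from the hydroxyl hydrogen
    h = thr.atom("HG1").coords
    direction = np.array([0.94, -0.22, 0.26])
    direction /= np.linalg.norm(direction)
    asp = Residue("ASP", 201, atoms=[
        Atom("OD2", "O", h + 1.81 * direction, 1.52, -0.5),
    ])
    return MolecularStructure(chains={"C": [thr, asp]})
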