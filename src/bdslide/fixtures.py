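"""Small deterministic systems for tests and examples."""

from __future__ import annotations

import numpy as np

from .model import (SystemSpec, Topology, assemble_system, build_dna,
                    build_protein)


class UnknownFixtureError(KeyError):
    pass


def _bare_system(positions, sigma, stokes, charge, names):
    n = len(positions)
    return SystemSpec(np.asarray(positions, float), np.asarray(sigma, float),
                      np.asarray(stokes, float), np.asarray(charge, float),
                      np.zeros(n, np.int64) + np.arange(n),  # one molecule each
                      np.zeros(n, np.int64), list(names), Topology())


def make_fixture(name: str) -> SystemSpec:
    """Named small systems.

    ``single``   one neutral bead, a = 20 Å.
    ``dimer``    two beads, a = 20 Å, 50 Å apart (separate molecules).
    ``dna20``    ideal 20-residue CG-DNA (40 beads).
    ``protein40``three-bead protein, a(PBP) = 40 Å, q(DBP) = 8.
    ``mini``     20-residue DNA + docked protein (43 beads).
    """
    if name == "single":
        return _bare_system([[0.0, 0.0, 0.0]], [10.0], [20.0], [0.0], ["X"])
    if name == "dimer":
        return _bare_system([[0.0, 0.0, 0.0], [50.0, 0.0, 0.0]],
                            [10.0, 10.0], [20.0, 20.0], [0.0, 0.0],
                            ["X", "X"])
    if name == "dna20":
        return build_dna(20)
    if name == "protein40":
        return build_protein(a_pbp=40.0, q_dbp=8.0)
    if name == "mini":
        return assemble_system(build_dna(20), build_protein(40.0, 8.0))
    raise UnknownFixtureError(name)


FIXTURE_NAMES = ("single", "dimer", "dna20", "protein40", "mini")
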