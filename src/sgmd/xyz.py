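"""Extended-XYZ structure I/O.

One frame: particle count, a comment line carrying ``Lattice="..."`` (nine
values, row-major lattice vectors; 2D boxes are padded with a unit z
vector), a ``Properties`` descriptor and free key=value pairs, then one row
per particle. Coordinates are written with 17 significant digits so a
write/read round trip is bitwise exact.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

__all__ = ["Frame", "write_xyz", "read_xyz", "write_structure", "read_structure"]


@dataclass
class Frame:
    positions: np.ndarray  # (n, D) Cartesian
    box: np.ndarray  # (D, D)
    dimension: int
    species: list[str]
    info: dict


def _format_lattice(box: np.ndarray, dimension: int) -> str:
    full = np.eye(3)
    full[:dimension, :dimension] = box
    return " ".join(f"{v:.17g}" for v in full.ravel())


def _quote(v) -> str:
    s = str(v)
    return f'"{s}"' if re.search(r"\s", s) else s


def write_xyz(path, frame: Frame, mode: str = "w") -> None:
    D = frame.dimension
    pos3 = np.zeros((len(frame.positions), 3))
    pos3[:, :D] = frame.positions
    info = dict(frame.info)
    info["dimension"] = D
    kv = " ".join(f"{k}={_quote(v)}" for k, v in info.items())
    with open(path, mode) as fh:
        fh.write(f"{len(frame.positions)}\n")
        fh.write(
            f'Lattice="{_format_lattice(frame.box, D)}" '
            f"Properties=species:S:1:pos:R:3 {kv}\n"
        )
        for sp, x in zip(frame.species, pos3):
            fh.write(f"{sp} {x[0]:.17g} {x[1]:.17g} {x[2]:.17g}\n")


def _parse_comment(line: str) -> dict:
    out = {}
    for m in re.finditer(r'(\S+?)=(?:"([^"]*)"|(\S+))', line):
        key, quoted, plain = m.groups()
        out[key] = quoted if quoted is not None else plain
    return out


def read_xyz(path) -> Frame:
    with open(path) as fh:
        n = int(fh.readline())
        header = _parse_comment(fh.readline())
        rows = [fh.readline().split() for _ in range(n)]
    lat = np.array([float(v) for v in header.pop("Lattice").split()]).reshape(3, 3)
    D = int(header.pop("dimension", 3))
    header.pop("Properties", None)
    species = [r[0] for r in rows]
    pos = np.array([[float(v) for v in r[1:4]] for r in rows])
    return Frame(
        positions=pos[:, :D],
        box=lat[:D, :D],
        dimension=D,
        species=species,
        info=header,
    )


def write_structure(state, path, expand: bool = False) -> None:
    """Write a SystemState: the asymmetric unit (default) or the expanded
    unit cell with ghosts tagged by species ``X``."""
    from . import forcefield

    info = {"group": state.group.identifier}
    if expand:
        cell = forcefield.ghost_positions(state)
        n_img = state.images.count
        root = cell.reshape(-1, n_img, state.dimension)[
            :, state.images.zero_index, :
        ]
        species = []
        for i in range(state.n):
            m = int(state._plan.multiplicities[i])
            species.extend(["LJ"] + ["X"] * (m - 1))
        frame = Frame(root, state.box, state.dimension, species, info)
    else:
        if state.wyckoff_assignments:
            info["wyckoff"] = ",".join(
                f"{i}:{lbl}" for i, lbl in sorted(state.wyckoff_assignments.items())
            )
        frame = Frame(
            state.asym_pos,
            state.box,
            state.dimension,
            ["LJ"] * state.n,
            info,
        )
    write_xyz(path, frame)


def read_structure(path):
    """Read a structure written by :func:`write_structure`; returns a Frame
    (the ``group`` and optional ``wyckoff`` assignments are in ``info``)."""
    return read_xyz(path)
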