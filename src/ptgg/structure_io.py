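"""Multi-model duplex structure I/O and duplex topology.

Structures are held column-wise: one shared atom table (a pandas DataFrame
with serial, name, residue_name, chain_id, residue_number, element) plus a
coordinate array.  An :class:`Ensemble` stacks the coordinates of models
that share one topology, which is the natural container for both NMR
families and MD frame dumps exported as PDB MODEL blocks.

Residue numbering follows the continuous 1..24 convention used throughout
the duplex analyses (strand I = 1..12, strand II = 13..24, residue i paired
with 25-i in the 12-mer fixture).  Files that number each chain from 1 are
renumbered on read and the mapping is kept on the ensemble.
"""

from __future__ import annotations

import dataclasses
import io
import warnings
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import PDB
from Bio.PDB.PDBExceptions import PDBConstructionException

from . import _refgeom
from .errors import PdbParseError, SelectionError, TopologyError

ATOM_COLUMNS = ["serial", "name", "residue_name", "chain_id", "residue_number", "element"]


@dataclasses.dataclass(frozen=True)
class AtomRecord:
    """One named atom of one conformer, coordinates in Angstrom."""

    serial: int
    name: str
    residue_name: str
    chain_id: str
    residue_number: int
    position: np.ndarray
    element: str

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError("position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)


class StructureModel:
    """Atom table plus one conformer's coordinates."""

    def __init__(self, atoms: pd.DataFrame, coords: np.ndarray, model_index: int = 0):
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(atoms), 3):
            raise ValueError("coords shape must be (n_atoms, 3)")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates must be finite")
        self.atoms = atoms.reset_index(drop=True)
        self.coords = coords
        self.model_index = int(model_index)
        self._index: dict[tuple[str, int, str], int] | None = None

    def __len__(self) -> int:
        return len(self.atoms)

    def _lookup(self) -> dict[tuple[str, int, str], int]:
        if self._index is None:
            keys = zip(self.atoms["chain_id"], self.atoms["residue_number"], self.atoms["name"])
            self._index = {}
            for i, key in enumerate(keys):
                if key in self._index:
                    raise TopologyError(f"duplicate atom {key}")
                self._index[key] = i
        return self._index

    def atom_index(self, residue_number: int, name: str, chain_id: str | None = None) -> int:
        lookup = self._lookup()
        if chain_id is not None:
            return lookup[(chain_id, residue_number, name)]
        hits = [i for (c, r, n), i in lookup.items() if r == residue_number and n == name]
        if not hits:
            raise KeyError(f"atom {name} of residue {residue_number} not found")
        if len(hits) > 1:
            raise KeyError(f"atom {name} of residue {residue_number} ambiguous across chains")
        return hits[0]

    def atom_position(self, residue_number: int, name: str) -> np.ndarray:
        return self.coords[self.atom_index(residue_number, name)]

    def residue_indices(self, residue_number: int) -> np.ndarray:
        return np.flatnonzero(self.atoms["residue_number"].to_numpy() == residue_number)

    def residue_base_letter(self, residue_number: int) -> str:
        rows = self.residue_indices(residue_number)
        if rows.size == 0:
            raise KeyError(f"residue {residue_number} not found")
        resname = self.atoms["residue_name"].iloc[rows[0]]
        try:
            return _refgeom.ONE_LETTER[resname]
        except KeyError:
            raise KeyError(f"residue {residue_number} ({resname}) is not a standard base")

    def records(self) -> list[AtomRecord]:
        return [
            AtomRecord(
                serial=int(row.serial), name=row.name, residue_name=row.residue_name,
                chain_id=row.chain_id, residue_number=int(row.residue_number),
                position=self.coords[i], element=row.element,
            )
            for i, row in enumerate(self.atoms.itertuples(index=False))
        ]

    def copy(self) -> "StructureModel":
        return StructureModel(self.atoms.copy(), self.coords.copy(), self.model_index)


@dataclasses.dataclass
class DuplexTopology:
    """Pairing and step layout of an antiparallel DNA duplex.

    ``pairs`` lists (residue_number_I, residue_number_II) in strand-I 5'->3'
    order; ``steps`` lists consecutive pair-index tuples (k, k+1).
    """

    sequence_I: str
    sequence_II: str
    pairs: list[tuple[int, int]]
    steps: list[tuple[int, int]]
    platinated_pair_indices: tuple[int, int] | None = None
    warnings: list[str] = dataclasses.field(default_factory=list)

    def __post_init__(self):
        n = len(self.pairs)
        if len(self.sequence_I) != n or len(self.sequence_II) != n:
            raise TopologyError("sequence lengths must match the pair list")
        # sequence_II is given 5'->3'; pair k joins strand I base k with
        # strand II base n-1-k, which must be its Watson-Crick complement
        for k, (base_i) in enumerate(self.sequence_I):
            partner = self.sequence_II[n - 1 - k]
            if _refgeom.COMPLEMENT[base_i] != partner:
                raise TopologyError(
                    f"pair {k}: {base_i} and {partner} are not Watson-Crick complementary"
                )
        for a, b in self.steps:
            if b != a + 1 or not (0 <= a < n - 1):
                raise TopologyError("steps must be consecutive pair indices")

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def pair_label(self, k: int) -> str:
        i, j = self.pairs[k]
        return f"{i}_{j}"

    def step_label(self, s: int) -> str:
        a, b = self.steps[s]
        return f"{self.pairs[a][0]}_{self.pairs[b][0]}"


class Ensemble:
    """Ordered conformers sharing one atom table and topology."""

    def __init__(
        self,
        atoms: pd.DataFrame,
        coords: np.ndarray,
        topology: DuplexTopology | None = None,
        source_tag: str = "",
        renumbering: dict | None = None,
    ):
        coords = np.asarray(coords, dtype=float)
        if coords.ndim != 3 or coords.shape[1] != len(atoms) or coords.shape[2] != 3:
            raise ValueError("coords shape must be (n_models, n_atoms, 3)")
        if coords.shape[0] < 1:
            raise ValueError("an ensemble needs at least one model")
        self.atoms = atoms.reset_index(drop=True)
        self.coords = coords
        self.topology = topology
        self.source_tag = source_tag
        self.renumbering = renumbering or {}

    @classmethod
    def from_models(
        cls,
        models: Sequence[StructureModel],
        topology: DuplexTopology | None = None,
        source_tag: str = "",
    ) -> "Ensemble":
        if not models:
            raise ValueError("an ensemble needs at least one model")
        ref = models[0].atoms
        for m in models[1:]:
            _check_same_atoms(ref, m.atoms)
        coords = np.stack([m.coords for m in models])
        return cls(ref, coords, topology=topology, source_tag=source_tag)

    def __len__(self) -> int:
        return self.coords.shape[0]

    def __getitem__(self, i: int) -> StructureModel:
        return StructureModel(self.atoms, self.coords[i], model_index=i)

    @property
    def models(self) -> list[StructureModel]:
        return [self[i] for i in range(len(self))]

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def with_topology(self, topology: DuplexTopology) -> "Ensemble":
        return Ensemble(self.atoms, self.coords, topology, self.source_tag, self.renumbering)


def _check_same_atoms(ref: pd.DataFrame, other: pd.DataFrame) -> None:
    key_cols = ["name", "residue_name", "chain_id", "residue_number"]
    a = list(map(tuple, ref[key_cols].itertuples(index=False)))
    b = list(map(tuple, other[key_cols].itertuples(index=False)))
    if a == b:
        return
    sa, sb = set(a), set(b)
    missing = sa ^ sb
    if missing:
        atom = sorted(missing)[0]
        raise TopologyError(f"models have mismatched atom sets; first mismatch: {atom}")
    raise TopologyError("models share atoms but order them differently")


def _normalize_atom_name(name: str) -> str:
    # accept the asterisk sugar dialect (C1* etc.), normalize to primes
    return name.strip().replace("*", "'")


def _prevalidate_pdb(path: Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM", "HETATM")):
                try:
                    float(line[30:38]), float(line[38:46]), float(line[46:54])
                except (ValueError, IndexError):
                    raise PdbParseError("unparseable coordinate fields", lineno)


def read_pdb_ensemble(path: str | Path, source_tag: str | None = None) -> Ensemble:
    """Read a (multi-)model PDB file into an :class:`Ensemble`.

    Models must share an identical atom list and ordering.  Atom names in
    the asterisk dialect are normalized to primes; chains that each start
    at residue 1 are renumbered into the continuous 1..24 convention with
    the mapping recorded on ``ensemble.renumbering``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _prevalidate_pdb(path)
    parser = PDB.PDBParser(QUIET=True)
    try:
        structure = parser.get_structure(path.stem, str(path))
    except PDBConstructionException as exc:  # pragma: no cover - parser detail
        raise PdbParseError(str(exc))
    models = []
    for model in structure:
        rows, coords = [], []
        serial = 0
        for chain in model:
            for residue in chain:
                for atom in residue:
                    serial += 1
                    name = _normalize_atom_name(atom.get_name())
                    element = atom.element.strip().capitalize() if atom.element.strip() else \
                        _refgeom.element_of(name)
                    rows.append((serial, name, residue.get_resname().strip(),
                                 chain.id if chain.id.strip() else "A",
                                 residue.get_id()[1], element))
                    coords.append(atom.get_coord())
        atoms = pd.DataFrame(rows, columns=ATOM_COLUMNS)
        models.append(StructureModel(atoms, np.asarray(coords, dtype=float),
                                     model_index=len(models)))
    if not models:
        raise PdbParseError("no models found in file")
    renumbering = _canonical_renumbering(models[0].atoms)
    if renumbering:
        for m in models:
            key = list(zip(m.atoms["chain_id"], m.atoms["residue_number"]))
            m.atoms["residue_number"] = [renumbering.get(k, k[1]) for k in key]
    ens = Ensemble.from_models(models, source_tag=source_tag or path.stem)
    ens.renumbering = renumbering
    return ens


def _canonical_renumbering(atoms: pd.DataFrame) -> dict[tuple[str, int], int]:
    """Map per-chain numbering onto the continuous convention.

    If a second DNA chain restarts numbering at values overlapping the
    first chain, its residues are shifted to continue the count.
    """
    chains = list(dict.fromkeys(atoms["chain_id"]))
    if len(chains) < 2:
        return {}
    mapping: dict[tuple[str, int], int] = {}
    offset = 0
    prev_max = None
    for chain in chains:
        resnums = sorted(set(atoms.loc[atoms["chain_id"] == chain, "residue_number"]))
        if prev_max is not None and resnums[0] <= prev_max:
            offset = prev_max - resnums[0] + 1
        for r in resnums:
            mapping[(chain, r)] = r + offset
        prev_max = resnums[-1] + offset
    if all(mapping[k] == k[1] for k in mapping):
        return {}
    return mapping


def _format_atom_name(name: str) -> str:
    if len(name) >= 4:
        return name[:4]
    return f" {name:<3s}"


def write_pdb_ensemble(path: str | Path, ensemble: Ensemble) -> None:
    """Write an ensemble as a standard multi-model PDB file (3-decimal grid)."""
    path = Path(path)
    standard = set(_refgeom.RESIDUE_NAME.values())
    lines: list[str] = []
    if len(ensemble) > 1:
        lines.append(f"NUMMDL    {len(ensemble):4d}")
    for i in range(len(ensemble)):
        if len(ensemble) > 1:
            lines.append(f"MODEL     {i + 1:4d}")
        for j, row in enumerate(ensemble.atoms.itertuples(index=False)):
            x, y, z = ensemble.coords[i, j]
            record = "ATOM  " if row.residue_name in standard else "HETATM"
            elem = row.element.upper()
            lines.append(
                f"{record}{row.serial:5d} {_format_atom_name(row.name)} "
                f"{row.residue_name:<3s} {row.chain_id:1s}{row.residue_number:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {elem:>2s}"
            )
        if len(ensemble) > 1:
            lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


def count_nummdl(path: str | Path) -> int | None:
    """Return the model count declared in the NUMMDL header, if any."""
    with open(path) as fh:
        for line in fh:
            if line.startswith("NUMMDL"):
                return int(line.split()[1])
            if line.startswith(("ATOM", "HETATM", "MODEL")):
                break
    return None


def infer_duplex_topology(
    model: StructureModel,
    platinated_residues: tuple[int, int] | None = None,
) -> DuplexTopology:
    """Derive the duplex pairing from a single conformer.

    Strands are taken from the two DNA chains (or one chain split at the
    numbering midpoint); pairing follows sequence complementarity of the
    antiparallel strands and is confirmed geometrically by the C1'-C1'
    distance (8.5-12.5 A for a Watson-Crick pair).  Failures of the
    geometric check on more than 20% of pairs are recorded as a warning
    but the complementarity-based pairing is kept.
    """
    standard = set(_refgeom.RESIDUE_NAME.values()) | set(_refgeom.ONE_LETTER)
    dna = model.atoms[model.atoms["residue_name"].isin(standard)]
    chains = list(dict.fromkeys(dna["chain_id"]))
    strands: list[list[int]] = []
    if len(chains) == 2:
        for chain in chains:
            resnums = sorted(set(dna.loc[dna["chain_id"] == chain, "residue_number"]))
            strands.append(resnums)
    elif len(chains) == 1:
        resnums = sorted(set(dna["residue_number"]))
        if len(resnums) % 2 != 0:
            raise TopologyError("single-chain input does not split into two equal strands")
        half = len(resnums) // 2
        strands = [resnums[:half], resnums[half:]]
        if len(strands[0]) < 2:
            raise TopologyError("input is a single strand, not a duplex")
    else:
        raise TopologyError(f"expected one or two DNA chains, found {len(chains)}")
    if len(strands) != 2 or len(strands[0]) != len(strands[1]):
        raise TopologyError("strands have unequal lengths")
    if len(strands[0]) < 2:
        raise TopologyError("input is a single strand, not a duplex")

    seq_I = "".join(model.residue_base_letter(r) for r in strands[0])
    seq_II = "".join(model.residue_base_letter(r) for r in strands[1])
    n = len(seq_I)
    pairs = [(strands[0][k], strands[1][n - 1 - k]) for k in range(n)]
    for k in range(n):
        if _refgeom.COMPLEMENT[seq_I[k]] != seq_II[n - 1 - k]:
            raise TopologyError(
                f"strands are not complementary at pair {k} "
                f"({seq_I[k]} vs {seq_II[n - 1 - k]})"
            )

    topo_warnings: list[str] = []
    bad = 0
    for i, j in pairs:
        try:
            d = np.linalg.norm(model.atom_position(i, "C1'") - model.atom_position(j, "C1'"))
        except KeyError:
            continue
        if not (8.5 <= d <= 12.5):
            bad += 1
    if bad > 0.2 * n:
        msg = f"geometric pairing check failed for {bad}/{n} pairs; keeping sequence pairing"
        topo_warnings.append(msg)
        warnings.warn(msg)

    plat = None
    if platinated_residues is not None:
        idx = []
        for r in platinated_residues:
            hits = [k for k, (i, j) in enumerate(pairs) if i == r or j == r]
            if not hits:
                raise TopologyError(f"platinated residue {r} is not in any pair")
            idx.append(hits[0])
        plat = (idx[0], idx[1])

    steps = [(k, k + 1) for k in range(n - 1)]
    return DuplexTopology(seq_I, seq_II, pairs, steps,
                          platinated_pair_indices=plat, warnings=topo_warnings)


Selector = Callable[..., bool]


def select_atoms(ensemble: Ensemble, selector: Selector) -> Ensemble:
    """Restrict an ensemble to atoms matching ``selector``.

    The selector is called with keyword arguments ``name``,
    ``residue_name``, ``chain_id``, ``residue_number`` and ``element`` and
    must return truth.  Atom ordering is preserved; an empty selection
    raises :class:`SelectionError`.
    """
    mask = np.array([
        bool(selector(name=row.name, residue_name=row.residue_name, chain_id=row.chain_id,
                      residue_number=row.residue_number, element=row.element))
        for row in ensemble.atoms.itertuples(index=False)
    ])
    if not mask.any():
        raise SelectionError("selector matched no atoms")
    atoms = ensemble.atoms.loc[mask].reset_index(drop=True)
    coords = ensemble.coords[:, mask, :]
    return Ensemble(atoms, coords, ensemble.topology, ensemble.source_tag, ensemble.renumbering)


def heavy_atom_selector(**atom) -> bool:
    """Non-hydrogen atoms, including any Pt moiety."""
    return atom["element"] != "H"


def residue_range_selector(residue_numbers: Iterable[int]) -> Selector:
    allowed = set(residue_numbers)

    def _select(**atom) -> bool:
        return atom["residue_number"] in allowed

    return _select


def central_four_selector(topology: DuplexTopology) -> Selector:
    """Atoms of the central four base pairs of the duplex."""
    n = topology.n_pairs
    central = range(n // 2 - 2, n // 2 + 2)
    residues = set()
    for k in central:
        residues.update(topology.pairs[k])
    return residue_range_selector(residues)
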