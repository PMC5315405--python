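"""Ingestion of Cα conformational ensembles from PDB files.

Structures are reduced to their Cα trace at parse time: all downstream
quantities (distance fluctuations, mechanical couplings) are defined on
Cα–Cα distances, so side chains are irrelevant. Multi-MODEL files (NMR
ensembles, MD frames exported as PDB models) expand into one structure
per MODEL.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionWarning
from Bio.PDB.Polypeptide import is_aa

logger = logging.getLogger("mechbridge")

GENERIC_NUMBER_RE = re.compile(r"^\d+x\d{2}$")

STATE_LABELS = ("active", "inactive", "partially_active", "unknown")

#: normalisation of manifest state spellings to canonical labels
_STATE_ALIASES = {
    "active": "active",
    "inactive": "inactive",
    "p. active": "partially_active",
    "p.active": "partially_active",
    "partially active": "partially_active",
    "partially_active": "partially_active",
    "active (?)": "active",
    "active(?)": "active",
    "unknown": "unknown",
}


@dataclass(frozen=True, order=True)
class ResidueKey:
    """Identity of one residue position within a structure.

    ``generic_number`` carries the cross-receptor generic position label
    in the ``AxBB`` form (helix number, position index within the helix,
    with the most conserved residue of each helix at 50).
    """

    chain_id: str
    seq_number: int
    insertion_code: str = ""
    residue_name: str = "UNK"
    generic_number: Optional[str] = None

    def __post_init__(self):
        if self.generic_number is not None and not GENERIC_NUMBER_RE.match(
            self.generic_number
        ):
            raise ValueError(
                f"generic number {self.generic_number!r} does not match AxBB"
            )

    @property
    def site(self) -> tuple:
        """Hashable identity used for residue correspondence (name excluded)."""
        return (self.chain_id, self.seq_number, self.insertion_code)

    def __str__(self) -> str:
        return f"{self.chain_id}:{self.residue_name}{self.seq_number}{self.insertion_code}"


@dataclass
class StructureModel:
    """One conformer: an ordered Cα trace with residue identities."""

    structure_id: str
    residues: list[ResidueKey]
    coordinates: np.ndarray  # (N, 3) in Å
    state_label: str = "unknown"

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.shape != (len(self.residues), 3):
            raise ValueError(
                f"{self.structure_id}: {len(self.residues)} residues but "
                f"coordinate array of shape {self.coordinates.shape}"
            )
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError(f"{self.structure_id}: non-finite coordinates")
        if self.state_label not in STATE_LABELS:
            raise ValueError(f"unknown state label {self.state_label!r}")
        sites = [r.site for r in self.residues]
        if len(set(sites)) != len(sites):
            raise ValueError(f"{self.structure_id}: duplicate residue keys")

    def __len__(self) -> int:
        return len(self.residues)

    def subset(self, indices: Sequence[int]) -> "StructureModel":
        return StructureModel(
            self.structure_id,
            [self.residues[i] for i in indices],
            self.coordinates[list(indices)],
            self.state_label,
        )


@dataclass
class Ensemble:
    """A set of conformers sharing one ordered residue list."""

    receptor_id: str
    members: list[StructureModel]
    residues: list[ResidueKey]

    def __post_init__(self):
        for m in self.members:
            if [r.site for r in m.residues] != [r.site for r in self.residues]:
                raise ValueError(
                    f"member {m.structure_id} does not match the common residue list"
                )

    def __len__(self) -> int:
        return len(self.members)

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    def coordinates(self) -> np.ndarray:
        """Stacked coordinates, shape (n_members, n_residues, 3)."""
        return np.stack([m.coordinates for m in self.members])

    def members_by_state(self, state: str) -> list[StructureModel]:
        return [m for m in self.members if m.state_label == state]


@dataclass
class ManifestRow:
    receptor_id: str
    path: Path
    state_label: str
    organism: str = ""


@dataclass
class DatasetManifest:
    rows: list[ManifestRow] = field(default_factory=list)

    def receptors(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.rows:
            seen.setdefault(r.receptor_id)
        return list(seen)

    def rows_for(self, receptor_id: str) -> list[ManifestRow]:
        return [r for r in self.rows if r.receptor_id == receptor_id]


def normalize_state(raw: str) -> str:
    key = raw.strip().lower()
    try:
        return _STATE_ALIASES[key]
    except KeyError:
        raise ValueError(f"unrecognised state label {raw!r}") from None


# ---------------------------------------------------------------------------
# parsing


def _model_to_trace(
    model, structure_id: str, chain_filter: Optional[str], state_label: str
) -> StructureModel:
    residues: list[ResidueKey] = []
    coords: list[np.ndarray] = []
    for chain in model:
        if chain_filter is not None and chain.id != chain_filter:
            continue
        for res in chain:
            if not is_aa(res, standard=True):
                continue
            hetflag, seq, icode = res.id
            if hetflag.strip():
                continue
            if "CA" not in res:
                logger.warning(
                    "%s: residue %s%s%s has no CA atom, skipped",
                    structure_id, chain.id, seq, icode.strip(),
                )
                continue
            ca = res["CA"]
            # DisorderedAtom: Bio.PDB selects highest occupancy, first on tie
            if ca.is_disordered():
                ca = ca.selected_child
            residues.append(
                ResidueKey(
                    chain_id=chain.id,
                    seq_number=seq,
                    insertion_code=icode.strip(),
                    residue_name=res.get_resname(),
                )
            )
            coords.append(ca.get_coord())
    if not residues:
        raise ValueError(f"{structure_id}: no Cα atoms found")
    # PDB prints 3 decimals; rounding recovers them exactly from the
    # parser's float32 values
    xyz = np.round(np.array(coords, dtype=float), 3)
    return StructureModel(structure_id, residues, xyz, state_label)


def load_structures(
    paths: Iterable[str | Path],
    chain_filter: Optional[str] = None,
    stride: int = 1,
    state_label: str = "unknown",
) -> list[StructureModel]:
    """Parse PDB files into Cα-trace structure models.

    Each MODEL record of a multi-model file becomes one :class:`StructureModel`
    (``<stem>#<model>``); ``stride`` subsamples those models. HETATM records,
    non-standard residues and non-Cα atoms are dropped; alternate locations
    resolve to the highest-occupancy conformer (first on tie); residues
    missing their Cα are skipped with a warning. A file containing no ATOM
    records is an error.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    parser = PDBParser(QUIET=True)
    models: list[StructureModel] = []
    for path in paths:
        path = Path(path)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", PDBConstructionWarning)
            structure = parser.get_structure(path.stem, str(path))
        pdb_models = list(structure)
        if not pdb_models:
            raise ValueError(f"{path}: no ATOM records")
        pdb_models = pdb_models[::stride]
        multi = len(pdb_models) > 1 or (len(structure) > 1)
        for m in pdb_models:
            sid = f"{path.stem}#{m.id}" if multi else path.stem
            models.append(_model_to_trace(m, sid, chain_filter, state_label))
    return models


def intersect_residues(
    models: Sequence[StructureModel], receptor_id: str = ""
) -> Ensemble:
    """Reduce models to their common residue set and build an ensemble.

    Correspondence is by (chain, author number, insertion code) with matching
    residue name — author numbering is trusted, no sequence alignment. Order
    follows the first model. A shared key whose residue name differs between
    models is excluded with a warning; an empty intersection is an error.
    """
    if len(models) < 2:
        raise ValueError("need at least 2 models for an ensemble")

    name_by_site: dict[tuple, str] = {}
    mismatched: set[tuple] = set()
    common: Optional[set] = None
    for m in models:
        sites = set()
        for r in m.residues:
            sites.add(r.site)
            prev = name_by_site.setdefault(r.site, r.residue_name)
            if prev != r.residue_name:
                mismatched.add(r.site)
        common = sites if common is None else (common & sites)
    assert common is not None
    for site in mismatched & common:
        logger.warning("residue %s excluded: residue-name mismatch across models",
                       site)
    common -= mismatched
    if not common:
        raise ValueError("empty residue intersection across models")

    first_order = [r.site for r in models[0].residues if r.site in common]
    index_of = {s: i for i, s in enumerate(first_order)}
    reduced = []
    for m in models:
        idx = sorted(
            (i for i, r in enumerate(m.residues) if r.site in common),
            key=lambda i: index_of[m.residues[i].site],
        )
        reduced.append(m.subset(idx))
    return Ensemble(receptor_id, reduced, list(reduced[0].residues))


# ---------------------------------------------------------------------------
# tabular inputs


def load_numbering_map(path: str | Path) -> dict[tuple[str, str, int], str]:
    """Read a generic-numbering map TSV.

    Columns: receptor_id, chain_id, seq_number, generic_number. Duplicate
    keys and malformed generic numbers are hard errors naming the line.
    """
    mapping: dict[tuple[str, str, int], str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if fields[0] == "receptor_id":
                continue
            if len(fields) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns")
            receptor_id, chain_id, seq_s, generic = fields
            if not GENERIC_NUMBER_RE.match(generic):
                raise ValueError(
                    f"{path}:{lineno}: malformed generic number {generic!r}"
                )
            key = (receptor_id, chain_id, int(seq_s))
            if key in mapping:
                raise ValueError(f"{path}:{lineno}: duplicate key {key}")
            mapping[key] = generic
    return mapping


def load_manifest(path: str | Path) -> DatasetManifest:
    """Read a dataset manifest TSV (receptor_id, path, state, organism)."""
    base = Path(path).parent
    rows: list[ManifestRow] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] == "receptor_id":
                continue
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 columns")
            receptor_id, fpath, state = fields[:3]
            organism = fields[3] if len(fields) > 3 else ""
            p = Path(fpath)
            if not p.is_absolute():
                p = base / p
            if not p.exists():
                raise FileNotFoundError(f"{path}:{lineno}: {p} does not exist")
            rows.append(ManifestRow(receptor_id, p, normalize_state(state), organism))
    return DatasetManifest(rows)


def load_manifest_ensembles(
    manifest: DatasetManifest,
    chain_filter: Optional[str] = None,
    stride: int = 1,
    numbering: Optional[Mapping[tuple[str, str, int], str]] = None,
) -> dict[str, Ensemble]:
    """Build one ensemble per receptor named in the manifest."""
    ensembles: dict[str, Ensemble] = {}
    for receptor_id in manifest.receptors():
        models: list[StructureModel] = []
        for row in manifest.rows_for(receptor_id):
            models.extend(
                load_structures([row.path], chain_filter, stride, row.state_label)
            )
        ens = intersect_residues(models, receptor_id)
        if numbering is not None:
            ens = annotate_generic_numbers(ens, numbering)
        ensembles[receptor_id] = ens
    return ensembles


def annotate_generic_numbers(
    ensemble: Ensemble, numbering: Mapping[tuple[str, str, int], str]
) -> Ensemble:
    """Attach generic numbers from a (receptor, chain, seq) map to an ensemble."""
    new_res = []
    for r in ensemble.residues:
        gn = numbering.get((ensemble.receptor_id, r.chain_id, r.seq_number))
        new_res.append(replace(r, generic_number=gn) if gn else r)
    members = [
        StructureModel(m.structure_id, new_res, m.coordinates, m.state_label)
        for m in ensemble.members
    ]
    return Ensemble(ensemble.receptor_id, members, new_res)


# ---------------------------------------------------------------------------
# output


def write_pdb(model: StructureModel, path: str | Path) -> None:
    """Write a Cα trace as a single-model PDB file (3-decimal precision)."""
    with open(path, "w") as fh:
        _write_model_records(fh, model, serial_start=1)
        fh.write("END\n")


def write_ensemble_pdb(ensemble: Ensemble, path: str | Path) -> None:
    """Write all ensemble members as MODEL records of one PDB file."""
    with open(path, "w") as fh:
        for i, m in enumerate(ensemble.members, start=1):
            fh.write(f"MODEL     {i:4d}\n")
            _write_model_records(fh, m, serial_start=1)
            fh.write("ENDMDL\n")
        fh.write("END\n")


def _write_model_records(fh, model: StructureModel, serial_start: int) -> None:
    serial = serial_start
    for r, xyz in zip(model.residues, model.coordinates):
        fh.write(
            f"ATOM  {serial:5d}  CA  {r.residue_name:>3s} {r.chain_id:1s}"
            f"{r.seq_number:4d}{r.insertion_code or ' ':1s}   "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
            f"          {' C':>2s}\n"
        )
        serial += 1
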