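"""Structure, sequence, distance-map and contact-list I/O.

The central objects are a target record (sequence plus optional domain
boundaries), a parsed structural model (Cα/Cβ coordinates with a
present-residue mask, so partial models are first-class), a symmetric L×L
distance map with an observation mask, and a list of predicted contacts
with CASP-style sequence-separation classes.

Residue numbering is 1-based throughout and ranges are inclusive. Missing
residues are carried as masks and never imputed.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionWarning

logger = logging.getLogger(__name__)

# CASP sequence-separation conventions: contacts with |i-j| < 6 are ignored,
# short range is 6-11, medium 12-23, long >= 24; contact threshold 8 A (strict).
MIN_SEPARATION = 6
SHORT_RANGE = (6, 11)
MEDIUM_RANGE = (12, 23)
LONG_RANGE_MIN = 24
CONTACT_THRESHOLD = 8.0

RANGE_CLASSES = ("short", "medium", "long")


class DataError(ValueError):
    """Raised for malformed or inconsistent input data."""


def classify_separation(sep: int) -> str | None:
    """Map a sequence separation |i-j| to its range class (None if < 6)."""
    if sep < MIN_SEPARATION:
        return None
    if sep <= SHORT_RANGE[1]:
        return "short"
    if sep <= MEDIUM_RANGE[1]:
        return "medium"
    return "long"


@dataclass(frozen=True)
class TargetRecord:
    """A prediction target: identifier, sequence and optional domains."""

    target_id: str
    sequence: str
    domains: tuple[tuple[int, int], ...] | None = None

    def __post_init__(self) -> None:
        if len(self.sequence) == 0:
            raise DataError("target sequence must be non-empty")
        if self.domains is not None:
            spans = sorted(self.domains)
            prev_end = 0
            for start, end in spans:
                if not (1 <= start <= end <= self.L):
                    raise DataError(
                        f"domain ({start}, {end}) outside target range [1, {self.L}]"
                    )
                if start <= prev_end:
                    raise DataError("domain ranges overlap")
                prev_end = end

    @property
    def L(self) -> int:
        return len(self.sequence)


@dataclass
class ProteinModel:
    """A (possibly partial) structural model as Cα/Cβ traces.

    ``ca_coords``/``cb_coords`` hold one row per *present* residue, in the
    order of ``residue_ids`` (strictly increasing, 1-based positions in the
    target sequence). ``present_mask`` is a boolean over all L target
    positions. For glycine (or when CB is missing) the Cβ slot holds the Cα.
    """

    target_id: str
    model_id: str
    residue_ids: np.ndarray
    ca_coords: np.ndarray
    cb_coords: np.ndarray
    length: int  # target length L

    def __post_init__(self) -> None:
        self.residue_ids = np.asarray(self.residue_ids, dtype=int)
        self.ca_coords = np.asarray(self.ca_coords, dtype=float)
        self.cb_coords = np.asarray(self.cb_coords, dtype=float)
        n = len(self.residue_ids)
        if self.ca_coords.shape != (n, 3) or self.cb_coords.shape != (n, 3):
            raise DataError("coordinate arrays must be (n_present, 3)")
        if not (np.isfinite(self.ca_coords).all() and np.isfinite(self.cb_coords).all()):
            raise DataError("coordinates must be finite")
        if n and (np.diff(self.residue_ids) <= 0).any():
            raise DataError("residue_ids must be strictly increasing")
        if n and (self.residue_ids[0] < 1 or self.residue_ids[-1] > self.length):
            raise DataError("residue_ids outside [1, L]")

    @property
    def n_present(self) -> int:
        return len(self.residue_ids)

    @property
    def present_mask(self) -> np.ndarray:
        mask = np.zeros(self.length, dtype=bool)
        mask[self.residue_ids - 1] = True
        return mask

    def coords(self, atom_scheme: str = "cb") -> np.ndarray:
        if atom_scheme == "cb":
            return self.cb_coords
        if atom_scheme == "ca":
            return self.ca_coords
        raise ValueError(f"unknown atom scheme {atom_scheme!r} (use 'ca' or 'cb')")

    def slice_domain(self, start: int, end: int, target_id: str | None = None) -> "ProteinModel":
        """Restrict to residues in [start, end] (1-based inclusive), renumbered to 1."""
        keep = (self.residue_ids >= start) & (self.residue_ids <= end)
        return ProteinModel(
            target_id=target_id or self.target_id,
            model_id=self.model_id,
            residue_ids=self.residue_ids[keep] - start + 1,
            ca_coords=self.ca_coords[keep],
            cb_coords=self.cb_coords[keep],
            length=end - start + 1,
        )


@dataclass
class DistanceMap:
    """Symmetric L×L distance matrix (Å) with an observation mask."""

    values: np.ndarray
    observed: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.observed = np.asarray(self.observed, dtype=bool)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise DataError("distance map must be square")
        if self.observed.shape != self.values.shape:
            raise DataError("observation mask shape mismatch")

    @property
    def size(self) -> int:
        return self.values.shape[0]

    @classmethod
    def full(cls, values: np.ndarray) -> "DistanceMap":
        values = np.asarray(values, dtype=float)
        return cls(values=values, observed=np.ones_like(values, dtype=bool))


@dataclass(frozen=True)
class Contact:
    i: int
    j: int
    probability: float
    range_class: str


@dataclass
class ContactList:
    """Predicted contacts with i < j (1-based) and separation classes."""

    contacts: list[Contact] = field(default_factory=list)

    def by_class(self, range_class: str) -> list[Contact]:
        if range_class == "all":
            return list(self.contacts)
        if range_class not in RANGE_CLASSES:
            raise ValueError(f"unknown range class {range_class!r}")
        return [c for c in self.contacts if c.range_class == range_class]

    def slice_domain(self, start: int, end: int) -> "ContactList":
        """Contacts fully inside [start, end], renumbered and reclassified."""
        out = []
        for c in self.contacts:
            if start <= c.i and c.j <= end:
                i, j = c.i - start + 1, c.j - start + 1
                rc = classify_separation(j - i)
                if rc is not None:
                    out.append(Contact(i, j, c.probability, rc))
        return ContactList(out)

    def __len__(self) -> int:
        return len(self.contacts)


# ---------------------------------------------------------------------------
# parsing


def read_fasta_target(path, target_id: str | None = None,
                      domains=None) -> TargetRecord:
    """Read the first record of a FASTA file as the target sequence."""
    from Bio import SeqIO

    rec = next(SeqIO.parse(str(path), "fasta"), None)
    if rec is None:
        raise DataError(f"no FASTA record in {path}")
    return TargetRecord(
        target_id=target_id or rec.id,
        sequence=str(rec.seq).upper(),
        domains=tuple(tuple(d) for d in domains) if domains else None,
    )


def parse_model(pdb_text: str, target: TargetRecord, model_id: str = "model") -> ProteinModel:
    """Parse PDB ATOM records into a :class:`ProteinModel`.

    Only the first MODEL and first chain are read (CASP models are
    single-chain). Cα is required for a residue to count as present; Cβ is
    taken from the CB atom when it exists and falls back to Cα (glycine, or
    a truncated side chain). Residue numbers must map into [1, L].
    """
    if "ATOM" not in pdb_text:
        raise DataError("no ATOM records in PDB input")
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PDBConstructionWarning)
        structure = parser.get_structure(model_id, io.StringIO(pdb_text))
    try:
        chain = next(iter(next(iter(structure))))
    except StopIteration:  # pragma: no cover - biopython yields no model
        raise DataError("no ATOM records in PDB input") from None

    ids, ca, cb = [], [], []
    for residue in chain:
        hetflag, resseq, _icode = residue.id
        if hetflag.strip():
            continue
        if "CA" not in residue:
            continue  # residues without Calpha are treated as missing
        if not (1 <= resseq <= target.L):
            raise DataError(
                f"residue index {resseq} outside target range [1, {target.L}]"
            )
        if ids and resseq <= ids[-1]:
            continue  # duplicate numbering / insertion codes: keep first
        ca_xyz = residue["CA"].get_coord().astype(float)
        cb_xyz = residue["CB"].get_coord().astype(float) if "CB" in residue else ca_xyz
        ids.append(resseq)
        ca.append(ca_xyz)
        cb.append(cb_xyz)
    if not ids:
        raise DataError("no ATOM records with Calpha atoms in PDB input")
    return ProteinModel(
        target_id=target.target_id,
        model_id=model_id,
        residue_ids=np.array(ids),
        ca_coords=np.array(ca),
        cb_coords=np.array(cb),
        length=target.L,
    )


THREE_LETTER = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR",
}


def write_model_pdb(model: ProteinModel, path, sequence: str | None = None) -> None:
    """Write a minimal PDB file with CA and CB ATOM records."""
    lines = []
    serial = 1
    for k, rid in enumerate(model.residue_ids):
        aa = sequence[rid - 1] if sequence else "A"
        resname = THREE_LETTER.get(aa, "ALA")
        for name, xyz in (("CA", model.ca_coords[k]), ("CB", model.cb_coords[k])):
            if name == "CB" and resname == "GLY":
                continue
            lines.append(
                f"ATOM  {serial:5d}  {name:<3s}{resname} A{rid:4d}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00           "
                f"{name[0]}"
            )
            serial += 1
    lines.append("TER")
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# distance maps


def compute_distance_map(model: ProteinModel, atom_scheme: str = "cb") -> DistanceMap:
    """Pairwise Euclidean distance map of a model (the MDM).

    Entries involving a missing residue are unobserved; the map is symmetric
    with a zero diagonal on observed entries.
    """
    from scipy.spatial.distance import squareform, pdist

    L = model.length
    values = np.zeros((L, L))
    present = model.present_mask
    coords = model.coords(atom_scheme)
    idx = model.residue_ids - 1
    if model.n_present >= 2:
        sub = squareform(pdist(coords))
        values[np.ix_(idx, idx)] = sub
    observed = np.outer(present, present)
    return DistanceMap(values=values, observed=observed)


def read_distance_map(path, L: int) -> DistanceMap:
    """Read a whitespace-delimited L×L matrix as a fully observed map.

    Mild asymmetry is repaired by averaging (m + mᵀ)/2; asymmetry beyond
    1e-6 is logged as a warning.
    """
    m = np.loadtxt(str(path), ndmin=2)
    if m.shape != (L, L):
        raise DataError(
            f"distance map shape mismatch: expected ({L}, {L}), found {m.shape}"
        )
    if (m < 0).any():
        raise DataError("distance map contains negative entries")
    asym = float(np.abs(m - m.T).max())
    if asym > 1e-6:
        logger.warning("distance map asymmetry %.3g repaired by averaging", asym)
    m = (m + m.T) / 2.0
    return DistanceMap.full(m)


def write_distance_map(dmap: DistanceMap, path) -> None:
    """Write map values at 6 decimal places (unobserved entries as 0)."""
    values = np.where(dmap.observed, dmap.values, 0.0)
    np.savetxt(str(path), values, fmt="%.6f")


# ---------------------------------------------------------------------------
# contacts


def read_rr(path, L: int) -> ContactList:
    """Read CASP RR-format contact predictions.

    Lines are ``i j d1 d2 p``; header/sequence lines are ignored. Pairs with
    sequence separation < 6 are dropped; the rest are classified as
    short (6-11), medium (12-23) or long (>= 24) range.
    """
    skip_tokens = {"PFRMAT", "TARGET", "AUTHOR", "REMARK", "METHOD", "MODEL", "END"}
    contacts: list[Contact] = []
    seen: set[tuple[int, int]] = set()
    with open(path) as fh:
        for line_no, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            fields = line.split()
            if fields[0].upper() in skip_tokens:
                continue
            if fields[0].isalpha():  # bare sequence line
                continue
            if len(fields) < 5:
                raise DataError(f"{path}:{line_no}: expected 'i j d1 d2 p'")
            i, j = int(fields[0]), int(fields[1])
            p = float(fields[4])
            if i == j:
                raise DataError(f"{path}:{line_no}: self-contact i == j == {i}")
            if not (0.0 <= p <= 1.0):
                raise DataError(f"{path}:{line_no}: probability {p} outside [0, 1]")
            if i > j:
                i, j = j, i
            if not (1 <= i and j <= L):
                raise DataError(f"{path}:{line_no}: pair ({i}, {j}) outside [1, {L}]")
            if (i, j) in seen:
                continue
            rc = classify_separation(j - i)
            if rc is None:
                continue
            seen.add((i, j))
            contacts.append(Contact(i, j, p, rc))
    return ContactList(contacts)


def write_rr(contacts: ContactList, path, sequence: str | None = None) -> None:
    lines = ["PFRMAT RR"]
    if sequence:
        lines.append(sequence)
    for c in contacts.contacts:
        lines.append(f"{c.i} {c.j} 0 8 {c.probability:.6f}")
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _separation_mask(L: int, range_class: str) -> np.ndarray:
    sep = np.abs(np.arange(L)[:, None] - np.arange(L)[None, :])
    if range_class == "short":
        return (sep >= SHORT_RANGE[0]) & (sep <= SHORT_RANGE[1])
    if range_class == "medium":
        return (sep >= MEDIUM_RANGE[0]) & (sep <= MEDIUM_RANGE[1])
    if range_class == "long":
        return sep >= LONG_RANGE_MIN
    if range_class == "all":
        return sep >= MIN_SEPARATION
    raise ValueError(f"unknown range class {range_class!r}")


def contacts_from_map(dmap: DistanceMap, threshold: float = CONTACT_THRESHOLD,
                      range_class: str = "all") -> set[tuple[int, int]]:
    """Observed pairs i < j of the given separation class with d < threshold."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    L = dmap.size
    mask = _separation_mask(L, range_class) & dmap.observed & (dmap.values < threshold)
    ii, jj = np.nonzero(np.triu(mask, k=1))
    return {(int(i) + 1, int(j) + 1) for i, j in zip(ii, jj)}
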