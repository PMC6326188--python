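"""Readers and writers for on-disk artifacts, plus the core domain types.

File formats
------------
* ΔΔG table (generic TSV): header ``site\\tresidue_number\\twt_aa\\tA\\tC...Y``,
  one row per site, ΔΔG in kcal/mol, amino-acid columns in fixed alphabetical
  one-letter order.
* FoldX "Dif" dialect: tab-delimited rows ``<WT><resnum><MUT>_<run>.pdb\\t<ddG>``
  with repeated runs per mutation; runs are averaged at read time and mapped
  onto the generic layout.
* Preference profile TSV: header ``site\\twt_aa\\tpi_A...pi_Y``; rows are points
  on the 20-simplex.
* Alignment map TSV: header ``site_a\\tsite_b\\tca_dist`` (Å).
* PDB coordinates: ATOM records only, first model of multi-model files,
  alternate locations resolved by highest occupancy then alphabetical altloc,
  hydrogens excluded.

All TSVs are UTF-8 with '.' decimal separators and round-trip within 1e-12 per
entry; PDB round-trips at the format's 3-decimal coordinate precision.
Internally site indices are 0-based and dense; author residue numbers are
retained for reporting only.
"""

from __future__ import annotations

import logging
import math
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from Bio.Data.IUPACData import protein_letters_1to3, protein_letters_3to1
from Bio.PDB import PDBParser

__all__ = [
    "AA_ALPHABET",
    "AA_INDEX",
    "N_AA",
    "ParseError",
    "ValidationError",
    "SiteRecord",
    "DdgMatrix",
    "PreferenceProfile",
    "Residue",
    "StructureModel",
    "AlignmentMap",
    "read_ddg_table",
    "write_ddg_table",
    "read_profile",
    "write_profile",
    "read_alignment",
    "write_alignment",
    "read_pdb",
    "write_pdb",
    "load_config",
    "setup_logging",
]

logger = logging.getLogger("ssapdiv")

#: The 20 standard amino acids in alphabetical one-letter order. Every matrix
#: column in the package follows this order.
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA_ALPHABET)}
N_AA = 20

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})


class ParseError(ValueError):
    """A file could not be parsed under the named dialect."""


class ValidationError(ValueError):
    """A value violates a domain-type invariant."""


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )


def load_config(path: str | Path) -> dict:
    """Load a YAML configuration document into a plain dict."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        cfg = {}
    if not isinstance(cfg, dict):
        raise ParseError(f"{path}: config must be a single YAML mapping")
    return cfg


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SiteRecord:
    """One protein site: dense 0-based index, author numbering, wildtype aa."""

    site_index: int
    residue_number: int
    wildtype_aa: str
    insertion_code: str = ""


@dataclass
class DdgMatrix:
    """Per-site × 20-amino-acid stability changes (ΔΔG, kcal/mol).

    ``values[r, a]`` is the change in folding free energy when site ``r`` is
    mutated from its wildtype to amino acid ``a`` (column order
    :data:`AA_ALPHABET`); the wildtype self-substitution is identically 0 by
    definition ΔΔG = ΔG_{r,a} − ΔG_{r,wt}. ``replicate_count`` records how
    many independent model builds were averaged per mutation (5 by
    convention); ``stderr`` optionally carries per-entry standard errors.
    """

    protein_id: str
    sites: list[SiteRecord]
    values: np.ndarray
    replicate_count: int = 5
    stderr: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def wildtype_sequence(self) -> str:
        return "".join(s.wildtype_aa for s in self.sites)

    def validate(self) -> "DdgMatrix":
        if self.values.shape != (len(self.sites), N_AA):
            raise ValidationError(
                f"ΔΔG matrix shape {self.values.shape} does not match "
                f"{len(self.sites)} sites × {N_AA} amino acids"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("ΔΔG matrix contains non-finite values")
        for rec in self.sites:
            if rec.wildtype_aa not in AA_INDEX:
                raise ValidationError(
                    f"site {rec.site_index}: unknown amino-acid code "
                    f"{rec.wildtype_aa!r}"
                )
            if self.values[rec.site_index, AA_INDEX[rec.wildtype_aa]] != 0.0:
                raise ValidationError(
                    f"site {rec.site_index}: wildtype self-ΔΔG must be 0"
                )
        return self


@dataclass
class PreferenceProfile:
    """L×20 row-stochastic matrix π of site-specific amino acid preferences."""

    protein_id: str
    sites: list[SiteRecord]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def validate(self, tol: float = 1e-9) -> "PreferenceProfile":
        if self.values.shape != (len(self.sites), N_AA):
            raise ValidationError(
                f"profile shape {self.values.shape} does not match "
                f"{len(self.sites)} sites × {N_AA} amino acids"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("profile contains non-finite values")
        if np.any(self.values < 0):
            raise ValidationError("profile contains negative preferences")
        sums = self.values.sum(axis=1)
        bad = np.nonzero(np.abs(sums - 1.0) > tol)[0]
        if bad.size:
            raise ValidationError(
                f"profile rows {bad.tolist()} do not sum to 1 "
                f"(sums {sums[bad].tolist()})"
            )
        return self


@dataclass
class Residue:
    """One residue of a structure: author number, one-letter aa, atoms in Å."""

    number: int
    aa: str
    atoms: dict[str, np.ndarray]
    insertion_code: str = ""

    @property
    def ca(self) -> np.ndarray | None:
        return self.atoms.get("CA")

    def atom_coords(self, sidechain_only: bool = False) -> np.ndarray:
        names = [
            n
            for n in self.atoms
            if not (sidechain_only and n in BACKBONE_ATOMS)
        ]
        if not names:
            return np.empty((0, 3))
        return np.stack([self.atoms[n] for n in names])


@dataclass
class StructureModel:
    """Protein 3D coordinates for a single chain (PDB convention, Å)."""

    structure_id: str
    chain_id: str
    residues: list[Residue]
    source: str = ""

    @property
    def n_sites(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    def ca_sites(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (site indices with a Cα atom, their coordinates)."""
        idx = [i for i, r in enumerate(self.residues) if r.ca is not None]
        if not idx:
            return np.empty(0, dtype=int), np.empty((0, 3))
        coords = np.stack([self.residues[i].ca for i in idx])
        return np.asarray(idx, dtype=int), coords

    def validate(self) -> "StructureModel":
        for i, res in enumerate(self.residues):
            for name, xyz in res.atoms.items():
                if not np.all(np.isfinite(xyz)):
                    raise ValidationError(
                        f"residue {i} atom {name}: non-finite coordinates"
                    )
        return self


@dataclass
class AlignmentMap:
    """Equivalent-site pairing between two homologs.

    ``pairs`` holds ``(site_a, site_b, ca_distance)`` triples; site pairs are
    equivalent when their Cα atoms are within ``threshold`` Å (default 3.5)
    after optimal superposition. ``sequence_divergence`` is the fraction of
    pairs whose amino acids differ; coverage is the fraction of each
    protein's sites that are paired.
    """

    pairs: list[tuple[int, int, float]]
    unpaired_a: list[int] = field(default_factory=list)
    unpaired_b: list[int] = field(default_factory=list)
    sequence_divergence: float | None = None
    coverage_a: float | None = None
    coverage_b: float | None = None
    threshold: float = 3.5

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def a_to_b(self) -> dict[int, int]:
        return {sa: sb for sa, sb, _ in self.pairs}

    def b_to_a(self) -> dict[int, int]:
        return {sb: sa for sa, sb, _ in self.pairs}

    def distances(self) -> np.ndarray:
        return np.asarray([d for _, _, d in self.pairs], dtype=float)

    def validate(self) -> "AlignmentMap":
        seen_a: set[int] = set()
        seen_b: set[int] = set()
        for sa, sb, d in self.pairs:
            if sa in seen_a or sb in seen_b:
                raise ValidationError(
                    f"site pair ({sa}, {sb}): sites may appear in at most one pair"
                )
            seen_a.add(sa)
            seen_b.add(sb)
            if d > self.threshold + 1e-9:
                raise ValidationError(
                    f"site pair ({sa}, {sb}): Cα distance {d:.3f} Å exceeds "
                    f"the equivalence threshold {self.threshold} Å"
                )
        return self

    @classmethod
    def identity(cls, n_sites: int, seq_a: str | None = None,
                 seq_b: str | None = None) -> "AlignmentMap":
        """Trivial self-alignment of ``n_sites`` sites at distance 0."""
        am = cls(pairs=[(i, i, 0.0) for i in range(n_sites)],
                 coverage_a=1.0, coverage_b=1.0)
        if seq_a is not None and seq_b is not None:
            mism = sum(1 for a, b in zip(seq_a, seq_b) if a != b)
            am.sequence_divergence = mism / n_sites
        else:
            am.sequence_divergence = 0.0
        return am


# ---------------------------------------------------------------------------
# ΔΔG tables
# ---------------------------------------------------------------------------

_DDG_HEADER = ["site", "residue_number", "wt_aa", *AA_ALPHABET]


def read_ddg_table(path: str | Path, dialect: str = "generic_tsv",
                   protein_id: str | None = None) -> DdgMatrix:
    """Read a ΔΔG table.

    ``dialect`` is ``generic_tsv`` (one row per site) or ``foldx_dif``
    (per-run mutation energies, averaged). Wildtype self-entries are forced
    to 0 regardless of the input, with a logged warning if they were not.
    """
    path = Path(path)
    pid = protein_id if protein_id is not None else path.stem
    if dialect == "generic_tsv":
        return _read_generic_ddg(path, pid)
    if dialect == "foldx_dif":
        return _read_foldx_dif(path, pid)
    raise ValueError(f"unknown ΔΔG dialect {dialect!r}")


def _read_generic_ddg(path: Path, pid: str) -> DdgMatrix:
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines or lines[0].split("\t") != _DDG_HEADER:
        raise ParseError(f"{path}: line 1: expected header "
                         f"{'/'.join(_DDG_HEADER[:3])}/A.../Y")
    sites: list[SiteRecord] = []
    rows: list[list[float]] = []
    for ln, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        f = line.split("\t")
        if len(f) != 3 + N_AA:
            raise ParseError(
                f"{path}: line {ln}: expected {3 + N_AA} fields, got {len(f)}"
            )
        try:
            resnum = int(f[1])
        except ValueError as exc:
            raise ParseError(f"{path}: line {ln}: bad residue number {f[1]!r}") from exc
        wt = f[2].strip()
        if wt not in AA_INDEX:
            raise ValidationError(f"{path}: line {ln}: unknown amino-acid code {wt!r}")
        try:
            vals = [float(x) for x in f[3:]]
        except ValueError as exc:
            raise ParseError(f"{path}: line {ln}: non-numeric ΔΔG value") from exc
        if not all(math.isfinite(v) for v in vals):
            raise ValidationError(f"{path}: line {ln}: non-finite ΔΔG value")
        sites.append(SiteRecord(len(sites), resnum, wt))
        rows.append(vals)
    if not sites:
        raise ParseError(f"{path}: no data rows")
    values = np.asarray(rows, dtype=float)
    _force_wildtype_zero(values, sites, str(path))
    return DdgMatrix(pid, sites, values).validate()


_DIF_ROW = re.compile(
    r"^([A-Za-z])(\d+)([A-Za-z])_(\d+)\.pdb\t(-?(?:\d+\.?\d*|\.\d+)(?:[eE][+-]?\d+)?)\s*$"
)


def _read_foldx_dif(path: Path, pid: str) -> DdgMatrix:
    per_mut: dict[tuple[int, str], list[float]] = {}
    wt_of: dict[int, str] = {}
    n_data = 0
    for ln, line in enumerate(path.read_text(encoding="utf-8").splitlines(), start=1):
        if not line.strip():
            continue
        m = _DIF_ROW.match(line)
        if m is None:
            if line.split("\t")[0].endswith(".pdb"):
                raise ParseError(f"{path}: line {ln}: malformed Dif row")
            continue  # header / summary lines
        wt, resnum, mut = m.group(1).upper(), int(m.group(2)), m.group(3).upper()
        if wt not in AA_INDEX:
            raise ValidationError(f"{path}: line {ln}: unknown amino-acid code {wt!r}")
        if mut not in AA_INDEX:
            raise ValidationError(f"{path}: line {ln}: unknown amino-acid code {mut!r}")
        if wt_of.setdefault(resnum, wt) != wt:
            raise ValidationError(
                f"{path}: line {ln}: conflicting wildtype for residue {resnum}"
            )
        per_mut.setdefault((resnum, mut), []).append(float(m.group(5)))
        n_data += 1
    if not n_data:
        raise ParseError(f"{path}: no Dif data rows")
    resnums = sorted(wt_of)
    sites = [SiteRecord(i, rn, wt_of[rn]) for i, rn in enumerate(resnums)]
    gaps = []
    for rec in sites:
        missing = [a for a in AA_ALPHABET
                   if a != rec.wildtype_aa and (rec.residue_number, a) not in per_mut]
        if missing:
            gaps.append(f"residue {rec.residue_number}: {''.join(missing)}")
    if gaps:
        raise ValidationError(f"{path}: missing mutations — " + "; ".join(gaps))
    values = np.zeros((len(sites), N_AA))
    stderr = np.zeros((len(sites), N_AA))
    max_runs = 1
    any_multi = False
    for rec in sites:
        for a in AA_ALPHABET:
            if a == rec.wildtype_aa:
                continue
            runs = per_mut[(rec.residue_number, a)]
            values[rec.site_index, AA_INDEX[a]] = float(np.mean(runs))
            max_runs = max(max_runs, len(runs))
            if len(runs) >= 2:
                any_multi = True
                stderr[rec.site_index, AA_INDEX[a]] = float(
                    np.std(runs, ddof=1) / math.sqrt(len(runs))
                )
    return DdgMatrix(pid, sites, values, replicate_count=max_runs,
                     stderr=stderr if any_multi else None).validate()


def _force_wildtype_zero(values: np.ndarray, sites: list[SiteRecord],
                         source: str) -> None:
    for rec in sites:
        j = AA_INDEX[rec.wildtype_aa]
        if values[rec.site_index, j] != 0.0:
            logger.warning(
                "%s: site %d wildtype self-ΔΔG %.4g forced to 0",
                source, rec.site_index, values[rec.site_index, j],
            )
            values[rec.site_index, j] = 0.0


def write_ddg_table(ddg: DdgMatrix, path: str | Path) -> None:
    ddg.validate()
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_DDG_HEADER) + "\n")
        for rec, row in zip(ddg.sites, ddg.values):
            fh.write(
                f"{rec.site_index}\t{rec.residue_number}\t{rec.wildtype_aa}\t"
                + "\t".join(f"{v:.17g}" for v in row) + "\n"
            )


# ---------------------------------------------------------------------------
# Preference profiles
# ---------------------------------------------------------------------------

_PROFILE_HEADER = ["site", "wt_aa", *[f"pi_{a}" for a in AA_ALPHABET]]


def read_profile(path: str | Path, protein_id: str | None = None) -> PreferenceProfile:
    """Read a preference-profile TSV; rows are renormalized if they sum to 1
    within 1e-6, otherwise a validation error is raised."""
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines or lines[0].split("\t") != _PROFILE_HEADER:
        raise ParseError(f"{path}: line 1: expected header site/wt_aa/pi_A...pi_Y")
    sites: list[SiteRecord] = []
    rows: list[np.ndarray] = []
    for ln, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        f = line.split("\t")
        if len(f) != 2 + N_AA:
            raise ParseError(f"{path}: line {ln}: expected {2 + N_AA} fields")
        wt = f[1].strip()
        if wt not in AA_INDEX:
            raise ValidationError(f"{path}: line {ln}: unknown amino-acid code {wt!r}")
        try:
            row = np.asarray([float(x) for x in f[2:]])
        except ValueError as exc:
            raise ParseError(f"{path}: line {ln}: non-numeric preference") from exc
        if np.any(row < 0):
            raise ValidationError(f"{path}: line {ln}: negative preference")
        s = row.sum()
        if abs(s - 1.0) > 1e-6:
            raise ValidationError(
                f"{path}: line {ln}: row sums to {s:.8g}, not 1 within 1e-6"
            )
        sites.append(SiteRecord(len(sites), len(sites) + 1, wt))
        rows.append(row / s)
    if not sites:
        raise ParseError(f"{path}: no data rows")
    pid = protein_id if protein_id is not None else path.stem
    return PreferenceProfile(pid, sites, np.stack(rows)).validate()


def write_profile(profile: PreferenceProfile, path: str | Path) -> None:
    profile.validate()
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_PROFILE_HEADER) + "\n")
        for rec, row in zip(profile.sites, profile.values):
            fh.write(f"{rec.site_index}\t{rec.wildtype_aa}\t"
                     + "\t".join(f"{v:.17g}" for v in row) + "\n")


# ---------------------------------------------------------------------------
# Alignment maps
# ---------------------------------------------------------------------------

_ALN_HEADER = ["site_a", "site_b", "ca_dist"]


def read_alignment(path: str | Path, threshold: float = 3.5) -> AlignmentMap:
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines or lines[0].split("\t") != _ALN_HEADER:
        raise ParseError(f"{path}: line 1: expected header site_a/site_b/ca_dist")
    pairs: list[tuple[int, int, float]] = []
    for ln, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        f = line.split("\t")
        if len(f) != 3:
            raise ParseError(f"{path}: line {ln}: expected 3 fields")
        try:
            pairs.append((int(f[0]), int(f[1]), float(f[2])))
        except ValueError as exc:
            raise ParseError(f"{path}: line {ln}: malformed pair") from exc
    return AlignmentMap(pairs, threshold=threshold).validate()


def write_alignment(alignment: AlignmentMap, path: str | Path) -> None:
    alignment.validate()
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_ALN_HEADER) + "\n")
        for sa, sb, d in alignment.pairs:
            fh.write(f"{sa}\t{sb}\t{d:.17g}\n")


# ---------------------------------------------------------------------------
# PDB coordinates
# ---------------------------------------------------------------------------


def _pick_altloc(disordered) -> object:
    """Resolve an alternate-location atom: highest occupancy, then altloc."""
    children = disordered.disordered_get_list()
    return sorted(children, key=lambda a: (-(a.get_occupancy() or 0.0),
                                           a.get_altloc()))[0]


def read_pdb(path: str | Path, chain: str = "A",
             structure_id: str | None = None) -> StructureModel:
    """Read one chain from a PDB file (first model, ATOM records only).

    HETATM records and hydrogens are ignored. Residues lacking a Cα atom are
    retained with a logged warning; Cα-based operations skip them.
    """
    path = Path(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = PDBParser(QUIET=True).get_structure(path.stem, str(path))
    try:
        model = next(iter(structure))  # first model only
    except StopIteration:
        raise ParseError(f"{path}: no models in file") from None
    chain_ids = [c.id for c in model]
    if chain not in chain_ids:
        raise ValidationError(
            f"{path}: chain {chain!r} absent (available: {chain_ids})"
        )
    residues: list[Residue] = []
    for res in model[chain]:
        if res.id[0] != " ":
            continue  # HETATM / water
        three = res.get_resname().strip().capitalize()
        aa = protein_letters_3to1.get(three)
        if aa is None:
            logger.warning("%s: skipping non-standard residue %s %s",
                           path, res.get_resname(), res.id[1])
            continue
        atoms: dict[str, np.ndarray] = {}
        for atom in res:
            if atom.is_disordered():
                atom = _pick_altloc(atom)
            if (atom.element or "").upper() in ("H", "D"):
                continue
            atoms[atom.get_name()] = np.asarray(atom.get_coord(), dtype=float)
        if "CA" not in atoms:
            logger.warning("%s: residue %s%s lacks a Cα atom; excluded from "
                           "Cα operations", path, res.id[1], res.id[2].strip())
        residues.append(Residue(res.id[1], aa, atoms, res.id[2].strip()))
    residues.sort(key=lambda r: (r.number, r.insertion_code))
    sid = structure_id if structure_id is not None else path.stem
    return StructureModel(sid, chain, residues, source=str(path)).validate()


def write_pdb(model: StructureModel, path: str | Path) -> None:
    """Write a minimal single-chain PDB file (ATOM records, one model)."""
    model.validate()
    with open(path, "w", encoding="utf-8") as fh:
        serial = 1
        for res in model.residues:
            three = protein_letters_1to3.get(res.aa, "UNK").upper()
            for name, xyz in res.atoms.items():
                pdb_name = f" {name:<3s}" if len(name) < 4 else name
                fh.write(
                    f"ATOM  {serial:5d} {pdb_name}{'':1s}{three:>3s} "
                    f"{model.chain_id:1s}{res.number:4d}"
                    f"{res.insertion_code or ' ':1s}   "
                    f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                    f"{1.0:6.2f}{0.0:6.2f}          {name[0]:>2s}\n"
                )
                serial += 1
        fh.write("TER\nEND\n")
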