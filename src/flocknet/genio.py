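"""Readers, writers and validation for genotype, exchange and pedigree data.

Microsatellite genotypes travel as Genepop files (the de-facto exchange
format of the population-genetics software family this package mirrors)
or as plain TSV; animal-exchange records and pedigrees are delimited
tables.  All analyses downstream key herds by *herd of birth*, which may
differ from the herd an animal was sampled in, so an explicit animal->herd
map can override the Genepop POP-block grouping.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Sentinel for a missing allele call.  Distinct from 0 so that an allele
#: literally coded "0" in an input file can never be silently valid.
MISSING: int = -1

#: Sentinel for an unknown parent in a pedigree record.
UNKNOWN = None


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class GenotypeTable:
    """Diploid microsatellite calls for a set of animals.

    Parameters
    ----------
    individuals : list of str
        Animal identifiers, in file order.
    loci : list of str
        Ordered locus names.
    calls : ndarray of shape (n_individuals, n_loci, 2), dtype int
        Allele codes (positive integers, e.g. fragment lengths);
        :data:`MISSING` marks an untyped allele copy.
    herd_of_birth : dict
        Animal id -> herd id; ``None`` when the birth herd is unknown
        (such animals are kept but excluded from herd-level analyses).
    breed : dict
        Animal id -> breed label.
    """

    individuals: list[str]
    loci: list[str]
    calls: np.ndarray
    herd_of_birth: dict[str, str | None]
    breed: dict[str, str]

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int64)
        n, l = len(self.individuals), len(self.loci)
        if self.calls.shape != (n, l, 2):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{n} individuals x {l} loci x 2"
            )
        bad = (self.calls <= 0) & (self.calls != MISSING)
        if bad.any():
            raise ValueError("allele codes must be positive integers or MISSING")
        for ind in self.individuals:
            if ind not in self.herd_of_birth:
                raise ValueError(f"no herd-of-birth entry for {ind!r}")
            if ind not in self.breed:
                raise ValueError(f"no breed entry for {ind!r}")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def herds(self) -> list[str]:
        """Distinct birth herds in first-appearance order (unknowns skipped)."""
        seen: dict[str, None] = {}
        for ind in self.individuals:
            h = self.herd_of_birth[ind]
            if h is not None:
                seen.setdefault(h, None)
        return list(seen)

    def herd_members(self) -> dict[str, list[int]]:
        """Herd id -> row indices of its members (unknown birth herd excluded)."""
        out: dict[str, list[int]] = {}
        for i, ind in enumerate(self.individuals):
            h = self.herd_of_birth[ind]
            if h is not None:
                out.setdefault(h, []).append(i)
        return out

    def subset(self, rows: Sequence[int]) -> "GenotypeTable":
        inds = [self.individuals[i] for i in rows]
        return GenotypeTable(
            individuals=inds,
            loci=list(self.loci),
            calls=self.calls[list(rows)].copy(),
            herd_of_birth={i: self.herd_of_birth[i] for i in inds},
            breed={i: self.breed[i] for i in inds},
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeTable):
            return NotImplemented
        return (
            self.individuals == other.individuals
            and self.loci == other.loci
            and np.array_equal(
                np.sort(self.calls, axis=2), np.sort(other.calls, axis=2)
            )
            and self.herd_of_birth == other.herd_of_birth
            and self.breed == other.breed
        )


@dataclass(frozen=True)
class ExchangeRecord:
    """A single reported animal exchange between two herds."""

    source_herd: str
    dest_herd: str
    direction_known: bool = True

    def __post_init__(self) -> None:
        if self.source_herd == self.dest_herd:
            raise ValueError(f"self-exchange for herd {self.source_herd!r}")


@dataclass(frozen=True)
class PedigreeRecord:
    """Animal with (possibly unknown) sire and dam."""

    animal: str
    sire: str | None = UNKNOWN
    dam: str | None = UNKNOWN


@dataclass
class ValidationReport:
    """Report-only cross-check of a genotype table against exchange records."""

    herd_counts: dict[str, int]
    below_threshold: list[str]
    network_only_herds: list[str]
    locus_missingness: dict[str, float]
    n_records: int
    n_undirected_edges: int
    notes: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Genepop
# ---------------------------------------------------------------------------

def _parse_genepop_field(tok: str, line_no: int) -> tuple[int, int, int]:
    """One genotype field -> (allele1, allele2, digit width)."""
    if len(tok) == 4:
        w = 2
    elif len(tok) == 6:
        w = 3
    else:
        raise FormatError(
            f"line {line_no}: genotype field {tok!r} is neither 4 nor 6 digits"
        )
    try:
        a1, a2 = int(tok[:w]), int(tok[w:])
    except ValueError as exc:
        raise FormatError(f"line {line_no}: non-numeric genotype field {tok!r}") from exc
    return (a1 if a1 > 0 else MISSING, a2 if a2 > 0 else MISSING, w)


def read_genepop(path: str | Path, herd_map: str | Path | None = None) -> GenotypeTable:
    """Read a Genepop (.gen) file into a :class:`GenotypeTable`.

    POP blocks become herds (``POP1``, ``POP2``, ...) unless *herd_map*
    — a delimited table with columns ``animal``, ``herd`` and optionally
    ``breed`` — overrides them.  Allele code 0 (``00``/``000``) is missing.
    """
    lines = Path(path).read_text().splitlines()
    if len(lines) < 3:
        raise FormatError("Genepop file too short")
    # locus names: one per line, or comma-separated on the second line
    loci: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().lower() != "pop":
        chunk = lines[i].strip()
        if chunk:
            loci.extend(s.strip() for s in chunk.split(",") if s.strip())
        i += 1
    if not loci:
        raise FormatError("no locus names before first POP line")

    individuals: list[str] = []
    calls: list[list[tuple[int, int]]] = []
    herd_of: dict[str, str | None] = {}
    pop_idx = 0
    width_seen: int | None = None
    while i < len(lines):
        if lines[i].strip().lower() == "pop":
            pop_idx += 1
            i += 1
            continue
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        if "," not in line:
            raise FormatError(f"line {i + 1}: missing ',' after sample id")
        ind_id, rest = line.split(",", 1)
        ind_id = ind_id.strip()
        toks = rest.split()
        if len(toks) != len(loci):
            raise FormatError(
                f"line {i + 1}: {len(toks)} genotype fields for {len(loci)} loci"
            )
        row = []
        for tok in toks:
            a1, a2, w = _parse_genepop_field(tok, i + 1)
            if width_seen is None:
                width_seen = w
            elif w != width_seen:
                raise FormatError(
                    f"line {i + 1}: mixed 2- and 3-digit allele encoding"
                )
            row.append((a1, a2))
        if ind_id in herd_of:
            raise FormatError(f"line {i + 1}: duplicate animal id {ind_id!r}")
        individuals.append(ind_id)
        calls.append(row)
        herd_of[ind_id] = f"POP{pop_idx}"
        i += 1
    if not individuals:
        raise FormatError("no samples found")

    arr = np.array(calls, dtype=np.int64)
    breed = {ind: "NA" for ind in individuals}
    if herd_map is not None:
        hm = _read_table(herd_map)
        cols = {c.lower(): c for c in hm.columns}
        if "animal" not in cols or "herd" not in cols:
            raise FormatError("herd map needs 'animal' and 'herd' columns")
        for _, r in hm.iterrows():
            a = str(r[cols["animal"]])
            if a in herd_of:
                h = r[cols["herd"]]
                herd_of[a] = None if pd.isna(h) or str(h) == "" else str(h)
                if "breed" in cols and not pd.isna(r[cols["breed"]]):
                    breed[a] = str(r[cols["breed"]])
    return GenotypeTable(individuals, loci, arr, herd_of, breed)


def write_genepop(
    gt: GenotypeTable,
    path: str | Path,
    title: str = "flocknet export",
    digits: int | None = None,
) -> None:
    """Write a Genepop file; one POP block per birth herd, in table order.

    Animals with unknown birth herd go into a trailing ``POP`` block.
    """
    if digits is None:
        mx = int(gt.calls.max(initial=0))
        digits = 3 if mx > 99 else 2
    if int(gt.calls.max(initial=0)) >= 10**digits:
        raise ValueError(f"allele codes do not fit {digits}-digit encoding")

    def fmt(pair: np.ndarray) -> str:
        return "".join(
            f"{0 if a == MISSING else int(a):0{digits}d}" for a in pair
        )

    buf = io.StringIO()
    buf.write(title + "\n")
    for loc in gt.loci:
        buf.write(loc + "\n")
    blocks: dict[str | None, list[int]] = {}
    order: list[str | None] = []
    for idx, ind in enumerate(gt.individuals):
        h = gt.herd_of_birth[ind]
        if h not in blocks:
            blocks[h] = []
            order.append(h)
        blocks[h].append(idx)
    # unknown-herd block last for determinism
    if None in blocks:
        order = [h for h in order if h is not None] + [None]
    for h in order:
        buf.write("POP\n")
        for idx in blocks[h]:
            row = " ".join(fmt(gt.calls[idx, l]) for l in range(gt.n_loci))
            buf.write(f"{gt.individuals[idx]} , {row}\n")
    Path(path).write_text(buf.getvalue())


def write_herd_map(gt: GenotypeTable, path: str | Path) -> None:
    """Write the animal -> birth herd / breed map as TSV."""
    df = pd.DataFrame(
        {
            "animal": gt.individuals,
            "herd": [gt.herd_of_birth[i] or "" for i in gt.individuals],
            "breed": [gt.breed[i] for i in gt.individuals],
        }
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Delimited tables
# ---------------------------------------------------------------------------

def _read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python", dtype=str, keep_default_na=False)


_SOURCE_COLS = ("source_herd", "source", "from")
_DEST_COLS = ("dest_herd", "dest", "destination", "to")


def read_exchange_table(path: str | Path) -> list[ExchangeRecord]:
    """Read an animal-exchange edge table (TSV/CSV).

    Herds appearing only here (never genotyped) are retained: exchange
    networks legitimately include non-sampled herds.
    """
    df = _read_table(path)
    cols = {c.lower(): c for c in df.columns}
    src = next((cols[c] for c in _SOURCE_COLS if c in cols), None)
    dst = next((cols[c] for c in _DEST_COLS if c in cols), None)
    if src is None or dst is None:
        raise FormatError(
            f"exchange table needs source/dest herd columns, got {list(df.columns)}"
        )
    dk = cols.get("direction_known")
    records = []
    for i, r in df.iterrows():
        s, d = str(r[src]).strip(), str(r[dst]).strip()
        if not s or not d:
            raise FormatError(f"exchange row {i + 2}: empty herd id")
        if s == d:
            raise FormatError(f"exchange row {i + 2}: self-loop on herd {s!r}")
        known = True
        if dk is not None:
            known = str(r[dk]).strip().lower() not in ("0", "false", "no", "")
        records.append(ExchangeRecord(s, d, known))
    return records


def write_exchange_table(records: Iterable[ExchangeRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "source_herd": r.source_herd,
                "dest_herd": r.dest_herd,
                "direction_known": r.direction_known,
            }
            for r in records
        ],
        columns=["source_herd", "dest_herd", "direction_known"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_pedigree_table(path: str | Path) -> list[PedigreeRecord]:
    """Read a pedigree table with columns animal, sire, dam (empty = unknown)."""
    df = _read_table(path)
    cols = {c.lower(): c for c in df.columns}
    for need in ("animal", "sire", "dam"):
        if need not in cols:
            raise FormatError(f"pedigree table missing column {need!r}")
    records: list[PedigreeRecord] = []
    seen: set[str] = set()
    for i, r in df.iterrows():
        a = str(r[cols["animal"]]).strip()
        if not a:
            raise FormatError(f"pedigree row {i + 2}: empty animal id")
        if a in seen:
            raise FormatError(f"pedigree row {i + 2}: duplicate animal {a!r}")
        seen.add(a)
        s = str(r[cols["sire"]]).strip() or None
        d = str(r[cols["dam"]]).strip() or None
        records.append(PedigreeRecord(a, s, d))
    _check_pedigree_cycles(records)
    return records


def _check_pedigree_cycles(records: Sequence[PedigreeRecord]) -> None:
    """No animal may be its own ancestor within depth 2 (the depth the donor
    characterization uses)."""
    by_animal = {r.animal: r for r in records}
    for r in records:
        ancestors = set()
        for p in (r.sire, r.dam):
            if p is None:
                continue
            ancestors.add(p)
            pr = by_animal.get(p)
            if pr is not None:
                ancestors.update(x for x in (pr.sire, pr.dam) if x is not None)
        if r.animal in ancestors:
            raise FormatError(f"animal {r.animal!r} is its own ancestor (depth <= 2)")


def write_pedigree_table(records: Iterable[PedigreeRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {"animal": r.animal, "sire": r.sire or "", "dam": r.dam or ""}
            for r in records
        ],
        columns=["animal", "sire", "dam"],
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate_dataset(
    gt: GenotypeTable,
    exchanges: Sequence[ExchangeRecord],
    min_animals: int = 5,
) -> ValidationReport:
    """Cross-check genotypes against exchange records without mutating either.

    Flags herds below the *min_animals* analysis threshold (herd-level
    statistics require at least that many genotyped animals) and lists
    herds that occur only in the exchange network.
    """
    members = gt.herd_members()
    herd_counts = {h: len(idx) for h, idx in members.items()}
    below = sorted(h for h, c in herd_counts.items() if c < min_animals)
    exchange_herds = {r.source_herd for r in exchanges} | {r.dest_herd for r in exchanges}
    network_only = sorted(exchange_herds - set(herd_counts))
    missing = (gt.calls == MISSING).any(axis=2)
    locus_missingness = {
        loc: float(missing[:, j].mean()) for j, loc in enumerate(gt.loci)
    }
    edges = {frozenset((r.source_herd, r.dest_herd)) for r in exchanges}
    notes = []
    if not exchanges:
        notes.append("zero exchange records: network analyses will be empty")
    for h in below:
        notes.append(
            f"herd {h}: {herd_counts[h]} genotyped animals, "
            f"below {min_animals}-animal analysis threshold"
        )
    n_unknown_birth = sum(1 for i in gt.individuals if gt.herd_of_birth[i] is None)
    if n_unknown_birth:
        notes.append(
            f"{n_unknown_birth} animals with unknown herd of birth "
            "(excluded from herd-level analyses)"
        )
    return ValidationReport(
        herd_counts=herd_counts,
        below_threshold=below,
        network_only_herds=network_only,
        locus_missingness=locus_missingness,
        n_records=len(exchanges),
        n_undirected_edges=len(edges),
        notes=notes,
    )
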