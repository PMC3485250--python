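"""Readers and writers for every external artifact the pipeline touches.

Formats: FASTA for sequence alignments (via Biopython), GENEPOP for
microsatellite genotypes, tab-separated tables for sample metadata and
ABC reference tables, YAML for scenario/prior configuration.

Conventions:

* sample and locus order is file order everywhere; nothing is sorted
  silently, so permutation tests stay reproducible;
* GENEPOP allele codes are read as repeat numbers directly, with ``000``
  (or ``00``) meaning a missing allele;
* ``N`` and ``-`` in sequences mark missing sites, handled by pairwise
  deletion downstream.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "SampleTable",
    "SequenceAlignment",
    "MicrosatGenotypes",
    "ReferenceTable",
    "read_sequences",
    "write_sequences",
    "read_microsat_genepop",
    "write_microsat_genepop",
    "read_sample_table",
    "write_sample_table",
    "read_reference_table",
    "write_reference_table",
]

MISSING_ALLELE = 0
_VALID_BASES = frozenset("ACGTN-")


class DataFormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# domain containers


@dataclass
class SequenceAlignment:
    """Equal-length haplotyped sequences for one non-recombining locus."""

    locus_name: str
    sample_ids: list[str]
    sequences: list[str]

    def __post_init__(self) -> None:
        if len(self.sample_ids) != len(self.sequences):
            raise DataFormatError("sample_ids and sequences differ in length")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise DataFormatError("duplicate sample ids in alignment")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise DataFormatError(f"ragged sequence lengths: {sorted(lengths)}")
        for sid, seq in zip(self.sample_ids, self.sequences):
            bad = set(seq) - _VALID_BASES
            if bad:
                raise DataFormatError(f"illegal characters {bad} in {sid}")

    @property
    def n(self) -> int:
        return len(self.sequences)

    @property
    def length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    def to_array(self) -> np.ndarray:
        """(n, length) array of single-byte characters."""
        return np.frombuffer("".join(self.sequences).encode(), dtype="S1").reshape(
            self.n, self.length
        )

    def subset(self, sample_ids: Sequence[str]) -> "SequenceAlignment":
        index = {sid: i for i, sid in enumerate(self.sample_ids)}
        rows = [index[s] for s in sample_ids]
        return SequenceAlignment(
            self.locus_name,
            [self.sample_ids[i] for i in rows],
            [self.sequences[i] for i in rows],
        )


@dataclass
class MicrosatGenotypes:
    """Diploid repeat-number genotypes, individuals x loci x 2.

    Allele value 0 codes a missing allele; both copies of a cell are
    either observed or missing.
    """

    sample_ids: list[str]
    locus_names: list[str]
    genotypes: np.ndarray  # (n, L, 2) int
    populations: list[str] | None = None  # GENEPOP Pop-block labels

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=int)
        n, L = len(self.sample_ids), len(self.locus_names)
        if self.genotypes.shape != (n, L, 2):
            raise DataFormatError(
                f"genotype array shape {self.genotypes.shape} != ({n}, {L}, 2)"
            )
        if (self.genotypes < 0).any():
            raise DataFormatError("negative allele size")
        half_missing = (self.genotypes == MISSING_ALLELE).sum(axis=2) == 1
        if half_missing.any():
            raise DataFormatError("half-missing genotype cell")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise DataFormatError("duplicate sample ids")

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_names)

    def missing_mask(self) -> np.ndarray:
        """(n, L) boolean, True where the cell is missing."""
        return (self.genotypes == MISSING_ALLELE).all(axis=2)

    def subset(self, sample_ids: Sequence[str]) -> "MicrosatGenotypes":
        index = {sid: i for i, sid in enumerate(self.sample_ids)}
        rows = [index[s] for s in sample_ids]
        pops = [self.populations[i] for i in rows] if self.populations else None
        return MicrosatGenotypes(
            [self.sample_ids[i] for i in rows],
            list(self.locus_names),
            self.genotypes[rows],
            pops,
        )


@dataclass
class SampleTable:
    """Per-individual metadata: locality, group and coordinates."""

    sample_ids: list[str]
    locality_ids: list[str]
    group_labels: list[str]
    latitudes: list[float]
    longitudes: list[float]

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        for name in ("locality_ids", "group_labels", "latitudes", "longitudes"):
            if len(getattr(self, name)) != n:
                raise DataFormatError(f"{name} length != {n}")
        if len(set(self.sample_ids)) != n:
            raise DataFormatError("duplicate sample_id")
        if any(not g for g in self.group_labels):
            raise DataFormatError("empty group label")
        for lat, lon in zip(self.latitudes, self.longitudes):
            if not (-90 <= lat <= 90 and -180 <= lon <= 180):
                raise DataFormatError(f"coordinate out of range: ({lat}, {lon})")

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    @property
    def groups(self) -> list[str]:
        """Distinct group labels in order of first appearance."""
        seen: dict[str, None] = {}
        for g in self.group_labels:
            seen.setdefault(g)
        return list(seen)

    def group_of(self) -> dict[str, str]:
        return dict(zip(self.sample_ids, self.group_labels))

    def ids_in_group(self, group: str) -> list[str]:
        return [s for s, g in zip(self.sample_ids, self.group_labels) if g == group]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "locality_id": self.locality_ids,
                "group_label": self.group_labels,
                "latitude": self.latitudes,
                "longitude": self.longitudes,
            }
        )


@dataclass
class ReferenceTable:
    """Simulated (scenario, parameters, summary statistics) rows.

    ``norm`` holds the per-statistic scale used to normalise Euclidean
    distances: median absolute deviation, falling back to the standard
    deviation where the MAD is zero, and to 1 where both are.
    """

    scenario_ids: np.ndarray  # (rows,) str
    param_names: list[str]
    params: np.ndarray  # (rows, P) — NaN where a parameter is absent
    stat_names: list[str]
    stats: np.ndarray  # (rows, S)
    norm: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.scenario_ids = np.asarray(self.scenario_ids, dtype=object)
        self.params = np.asarray(self.params, dtype=float)
        self.stats = np.asarray(self.stats, dtype=float)
        if self.n_rows == 0:
            raise DataFormatError("reference table has no rows")
        if self.params.shape != (self.n_rows, len(self.param_names)):
            raise DataFormatError("parameter block shape mismatch")
        if self.stats.shape != (self.n_rows, len(self.stat_names)):
            raise DataFormatError("statistic block shape mismatch")
        if self.norm is None:
            self.norm = robust_scale(self.stats)
        else:
            self.norm = np.asarray(self.norm, dtype=float)

    @property
    def n_rows(self) -> int:
        return len(self.scenario_ids)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({"scenario": self.scenario_ids})
        for j, name in enumerate(self.param_names):
            df[f"param:{name}"] = self.params[:, j]
        for j, name in enumerate(self.stat_names):
            df[f"stat:{name}"] = self.stats[:, j]
        return df


def robust_scale(stats: np.ndarray) -> np.ndarray:
    """MAD per column; fall back to SD, then to 1, for degenerate columns."""
    med = np.median(stats, axis=0)
    mad = np.median(np.abs(stats - med), axis=0)
    sd = np.std(stats, axis=0)
    scale = np.where(mad > 0, mad, sd)
    return np.where(scale > 0, scale, 1.0)


# ---------------------------------------------------------------------------
# FASTA


def read_sequences(path: str | Path, locus_name: str) -> SequenceAlignment:
    """Read an aligned FASTA file; no alignment is performed.

    Mixed-case bases are upper-cased. Raises :class:`DataFormatError` on
    an empty file, ragged lengths or characters outside ``ACGTN-``.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise DataFormatError(f"no FASTA records in {path}")
    ids = [r.id for r in records]
    seqs = [str(r.seq).upper() for r in records]
    return SequenceAlignment(locus_name, ids, seqs)


def write_sequences(aln: SequenceAlignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, seq in zip(aln.sample_ids, aln.sequences):
            fh.write(f">{sid}\n{seq}\n")


# ---------------------------------------------------------------------------
# GENEPOP

_POP_RE = re.compile(r"^pop\s*$", re.IGNORECASE)


def read_microsat_genepop(path: str | Path) -> MicrosatGenotypes:
    """Parse a GENEPOP file (2- or 3-digit allele codes).

    Locus names may be one per line or comma-separated on one line.
    ``Pop`` separators delimit populations; the block label recorded for
    each individual is the id of the *last* individual's line prefix in
    common GENEPOP practice, but here simply ``pop<k>`` to stay neutral.
    """
    lines = Path(path).read_text().splitlines()
    if len(lines) < 3:
        raise DataFormatError("GENEPOP file too short")
    # line 0 is the title
    locus_names: list[str] = []
    i = 1
    while i < len(lines) and not _POP_RE.match(lines[i].strip()):
        chunk = lines[i].strip()
        if chunk:
            locus_names.extend(x.strip() for x in chunk.split(",") if x.strip())
        i += 1
    if i == len(lines):
        raise DataFormatError("no Pop block found")
    if not locus_names:
        raise DataFormatError("no locus names before first Pop")

    sample_ids: list[str] = []
    pops: list[str] = []
    rows: list[list[tuple[int, int]]] = []
    pop_idx = 0
    for line in lines[i:]:
        stripped = line.strip()
        if not stripped:
            continue
        if _POP_RE.match(stripped):
            pop_idx += 1
            continue
        if "," not in stripped:
            raise DataFormatError(f"individual line without comma: {stripped!r}")
        ind_id, geno_part = stripped.split(",", 1)
        fields = geno_part.split()
        if len(fields) != len(locus_names):
            raise DataFormatError(
                f"{ind_id.strip()}: {len(fields)} genotype fields for "
                f"{len(locus_names)} loci"
            )
        genos = [_parse_genepop_field(f, ind_id) for f in fields]
        sample_ids.append(ind_id.strip())
        pops.append(f"pop{pop_idx}")
        rows.append(genos)
    if pop_idx == 0:
        raise DataFormatError("no Pop block found")
    geno = np.array(rows, dtype=int)  # (n, L, 2)
    return MicrosatGenotypes(sample_ids, locus_names, geno, pops)


def _parse_genepop_field(field_: str, ind_id: str) -> tuple[int, int]:
    if len(field_) == 4:
        w = 2
    elif len(field_) == 6:
        w = 3
    else:
        raise DataFormatError(f"{ind_id.strip()}: malformed genotype field {field_!r}")
    if not field_.isdigit():
        raise DataFormatError(f"{ind_id.strip()}: non-numeric genotype {field_!r}")
    a1, a2 = int(field_[:w]), int(field_[w:])
    if (a1 == 0) != (a2 == 0):
        # a half-coded cell is treated as fully missing, GENEPOP convention
        return (MISSING_ALLELE, MISSING_ALLELE)
    return (a1, a2)


def write_microsat_genepop(
    geno: MicrosatGenotypes, path: str | Path, title: str = "karstabc export", digits: int = 3
) -> None:
    """Write GENEPOP, one Pop block per distinct population label."""
    if digits not in (2, 3):
        raise ValueError("digits must be 2 or 3")
    if (geno.genotypes >= 10**digits).any():
        raise DataFormatError("allele size too large for code width")
    pops = geno.populations or ["pop1"] * geno.n
    with open(path, "w") as fh:
        fh.write(title + "\n")
        for name in geno.locus_names:
            fh.write(name + "\n")
        current = None
        for i, sid in enumerate(geno.sample_ids):
            if pops[i] != current:
                fh.write("Pop\n")
                current = pops[i]
            cells = [
                f"{a1:0{digits}d}{a2:0{digits}d}"
                for a1, a2 in geno.genotypes[i]
            ]
            fh.write(f"{sid} , " + " ".join(cells) + "\n")


# ---------------------------------------------------------------------------
# sample table

_SAMPLE_COLS = ["sample_id", "locality_id", "group_label", "latitude", "longitude"]


def read_sample_table(path: str | Path) -> SampleTable:
    df = pd.read_csv(
        path, sep="\t", dtype={c: str for c in _SAMPLE_COLS[:3]},
        float_precision="round_trip",
    )
    missing = [c for c in _SAMPLE_COLS if c not in df.columns]
    if missing:
        raise DataFormatError(f"sample table missing columns: {missing}")
    try:
        lats = [float(x) for x in df["latitude"]]
        lons = [float(x) for x in df["longitude"]]
    except (TypeError, ValueError) as exc:
        raise DataFormatError(f"unparsable coordinate: {exc}") from exc
    return SampleTable(
        list(df["sample_id"]),
        list(df["locality_id"]),
        list(df["group_label"]),
        lats,
        lons,
    )


def write_sample_table(table: SampleTable, path: str | Path) -> None:
    table.to_dataframe().to_csv(path, sep="\t", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# reference table


def write_reference_table(table: ReferenceTable, path: str | Path) -> None:
    """Lossless TSV persistence (floats at full round-trip precision)."""
    table.to_dataframe().to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_reference_table(path: str | Path) -> ReferenceTable:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if "scenario" not in df.columns:
        raise DataFormatError("reference table lacks 'scenario' column")
    param_cols = [c for c in df.columns if c.startswith("param:")]
    stat_cols = [c for c in df.columns if c.startswith("stat:")]
    return ReferenceTable(
        df["scenario"].astype(str).to_numpy(dtype=object),
        [c[len("param:"):] for c in param_cols],
        df[param_cols].to_numpy(dtype=float),
        [c[len("stat:"):] for c in stat_cols],
        df[stat_cols].to_numpy(dtype=float),
    )
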