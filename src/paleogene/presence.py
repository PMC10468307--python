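"""Presence calling from protein-vs-CDS alignment hit tables.

The upstream search is TBLASTN-style: protein queries against nucleotide
coding sequences, so subject coordinates are nucleotide positions on the CDS.
A gene is called *present* in a species when at least one hit passes both the
identity and the subject-coverage threshold (80% / 80% by default, inclusive).
Coverage is measured on the nucleotide subject span and is orientation
invariant (minus-strand hits report start > end).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "AlignmentHit",
    "ThresholdConfig",
    "parse_hit_table",
    "read_species_map",
    "read_subject_lengths",
    "subject_coverage",
    "call_presence",
]


@dataclass(frozen=True)
class AlignmentHit:
    """One HSP from a protein-vs-CDS search.

    ``subject_start``/``subject_end`` are 1-based inclusive nucleotide
    coordinates; start > end encodes minus-strand orientation.
    """

    query_gene: str
    subject_species: str
    subject_seq: str
    percent_identity: float
    subject_start: int
    subject_end: int
    subject_length: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError(
                f"percent_identity {self.percent_identity} outside [0, 100]"
            )
        if self.subject_length <= 0:
            raise ValueError(f"subject_length {self.subject_length} must be > 0")
        lo = min(self.subject_start, self.subject_end)
        hi = max(self.subject_start, self.subject_end)
        if not 1 <= lo <= hi <= self.subject_length:
            raise ValueError(
                f"subject coordinates ({self.subject_start}, {self.subject_end}) "
                f"outside [1, {self.subject_length}]"
            )


@dataclass(frozen=True)
class ThresholdConfig:
    """Post-filter thresholds applied to raw hits (both inclusive ≥)."""

    min_identity: float = 80.0  # percent
    min_subject_coverage: float = 80.0  # percent

    def __post_init__(self) -> None:
        for name in ("min_identity", "min_subject_coverage"):
            v = getattr(self, name)
            if not 0.0 < v <= 100.0:
                raise ValueError(f"{name} must be in (0, 100], got {v}")


def subject_coverage(hit: AlignmentHit) -> float:
    """Fraction of the subject CDS spanned by the hit, in [0, 1]."""
    span = abs(hit.subject_end - hit.subject_start) + 1
    return span / hit.subject_length


def hit_passes(hit: AlignmentHit, cfg: ThresholdConfig) -> bool:
    return (
        hit.percent_identity >= cfg.min_identity
        and subject_coverage(hit) >= cfg.min_subject_coverage / 100.0
    )


def read_species_map(path) -> dict[str, str]:
    """Two-column TSV mapping subject-id prefix to taxon name."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#", names=["prefix", "taxon"],
        dtype=str,
    )
    return dict(zip(df["prefix"], df["taxon"]))


def read_subject_lengths(path) -> dict[str, int]:
    """Sidecar two-column TSV: subject id, subject length (nt)."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#", names=["sseqid", "slen"],
    )
    return dict(zip(df["sseqid"].astype(str), df["slen"].astype(int)))


def resolve_species(subject_seq: str, species_map: Mapping[str, str]) -> str:
    """Resolve a subject id to a taxon by longest matching prefix."""
    best = None
    for prefix, taxon in species_map.items():
        if subject_seq.startswith(prefix):
            if best is None or len(prefix) > len(best[0]):
                best = (prefix, taxon)
    if best is None:
        raise KeyError(
            f"subject id {subject_seq!r} matches no species_map prefix"
        )
    return best[1]


# column layouts accepted for hit tables, by column count
_COMPACT = ["qseqid", "sseqid", "pident", "sstart", "send", "slen"]
_OUTFMT6 = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def parse_hit_table(
    path,
    species_map: Mapping[str, str],
    subject_lengths: Mapping[str, int] | None = None,
) -> list[AlignmentHit]:
    """Read a BLAST-style tab-separated hit table.

    Accepted layouts (no header; ``#`` comment lines tolerated):

    * 5 columns ``qseqid sseqid pident sstart send`` (needs ``subject_lengths``)
    * 6 columns: the above plus ``slen``
    * 12 columns: standard outfmt-6 (needs ``subject_lengths``)
    * 13 columns: outfmt-6 plus ``slen`` appended

    Species are resolved from the subject id by longest prefix match against
    ``species_map``.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        return []
    ncol = df.shape[1]
    if ncol == 5:
        df.columns = _COMPACT[:5]
    elif ncol == 6:
        df.columns = _COMPACT
    elif ncol == 12:
        df.columns = _OUTFMT6
    elif ncol == 13:
        df.columns = _OUTFMT6 + ["slen"]
    else:
        raise ValueError(
            f"{path}: unrecognized hit-table layout with {ncol} columns"
        )
    if "slen" not in df.columns and subject_lengths is None:
        raise ValueError(
            f"{path}: no subject-length column and no sidecar length table"
        )

    hits: list[AlignmentHit] = []
    for row in df.itertuples(index=False):
        sseqid = str(row.sseqid)
        if "slen" in df.columns:
            slen = int(float(row.slen))
        else:
            assert subject_lengths is not None
            if sseqid not in subject_lengths:
                raise KeyError(f"no subject length for {sseqid!r}")
            slen = subject_lengths[sseqid]
        hits.append(
            AlignmentHit(
                query_gene=str(row.qseqid),
                subject_species=resolve_species(sseqid, species_map),
                subject_seq=sseqid,
                percent_identity=float(row.pident),
                subject_start=int(row.sstart),
                subject_end=int(row.send),
                subject_length=slen,
            )
        )
    return hits


def call_presence(
    hits: Iterable[AlignmentHit],
    genes: Sequence[str],
    species: Sequence[str],
    cfg: ThresholdConfig = ThresholdConfig(),
) -> pd.DataFrame:
    """Boolean gene × species detection matrix under the 80/80-style filter.

    A cell is True iff at least one hit for that (gene, species) pair passes
    both thresholds; merging of HSPs is deliberately not attempted.
    """
    matrix = pd.DataFrame(False, index=list(genes), columns=list(species))
    for hit in hits:
        if hit.query_gene not in matrix.index:
            raise KeyError(f"hit for unknown gene {hit.query_gene!r}")
        if hit.subject_species not in matrix.columns:
            raise KeyError(f"hit for unknown species {hit.subject_species!r}")
        if hit_passes(hit, cfg):
            matrix.loc[hit.query_gene, hit.subject_species] = True
    return matrix
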