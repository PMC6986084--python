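"""Interval filtering of tabular alignment hits and ACR candidate assembly.

The apomixis-controlling region (ACR) of *Paspalum* is syntenic to
marker-delimited segments of rice chromosomes 2 and 12.  Given BLAST-style
tabular hits of transcripts against the reference and the marker intervals
(as base-pair coordinates supplied by the user), :func:`filter_hits` keeps
hits at or below the e-value cutoff whose subject span overlaps an interval
by at least one base; the distinct query ids form the putative-ACR transcript
set.  :func:`build_candidates` intersects that set with the class-specific
and differentially expressed sets to produce the seed list used for the
coexpression subnetwork.

Coordinates are 1-based inclusive (the tabular alignment convention); BED
input is converted on read.  A subject start greater than the subject end
marks a minus-strand hit and is stored as-is.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import pandas as pd

HIT_COLUMNS = ("qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
               "qstart", "qend", "sstart", "send", "evalue", "bitscore")
_HIT_TYPES = (str, str, float, int, int, int, int, int, int, int, float, float)


@dataclass(frozen=True)
class Interval:
    """1-based inclusive reference interval."""

    chrom: str
    start: int
    end: int
    label: str

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"interval {self.label!r}: start > end")

    def overlaps(self, lo: int, hi: int, chrom: str) -> bool:
        return chrom == self.chrom and lo <= self.end and hi >= self.start


class IntervalSet:
    def __init__(self, intervals):
        intervals = list(intervals)
        labels = [iv.label for iv in intervals]
        if len(set(labels)) != len(labels):
            raise ValueError("interval labels must be unique")
        self._intervals = intervals

    def __iter__(self):
        return iter(self._intervals)

    def __len__(self):
        return len(self._intervals)

    @classmethod
    def from_bed(cls, path) -> "IntervalSet":
        """Read BED (0-based half-open); converted to 1-based inclusive."""
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
        ivs = []
        for i, row in df.iterrows():
            label = str(row[3]) if df.shape[1] > 3 else f"iv{i + 1}"
            ivs.append(Interval(str(row[0]), int(row[1]) + 1, int(row[2]), label))
        return cls(ivs)

    @classmethod
    def from_tsv(cls, path) -> "IntervalSet":
        """Read native TSV with header chrom/start/end/label, 1-based inclusive."""
        df = pd.read_csv(path, sep="\t", comment="#")
        return cls(Interval(str(r.chrom), int(r.start), int(r.end), str(r.label))
                   for r in df.itertuples(index=False))

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            [(iv.chrom, iv.start, iv.end, iv.label) for iv in self._intervals],
            columns=["chrom", "start", "end", "label"],
        ).to_csv(path, sep="\t", index=False)


def parse_hits(source, max_malformed_frac: float = 0.10) -> pd.DataFrame:
    """Parse a 12-column tabular alignment file into typed records.

    Malformed lines are skipped and reported in the returned frame's
    ``attrs["malformed"]`` as (line number, reason); if more than
    ``max_malformed_frac`` of non-empty lines are malformed, a ValueError
    summarising them is raised after the full pass.
    """
    if isinstance(source, (str, bytes)) and "\t" in str(source):
        fh = io.StringIO(str(source))
    else:
        fh = open(source)
    rows, malformed = [], []
    with fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                malformed.append((lineno, f"expected 12 columns, got {len(fields)}"))
                continue
            try:
                rows.append(tuple(t(v) for t, v in zip(_HIT_TYPES, fields)))
            except ValueError as exc:
                malformed.append((lineno, str(exc)))
    n_lines = len(rows) + len(malformed)
    if n_lines and len(malformed) / n_lines > max_malformed_frac:
        preview = "; ".join(f"line {ln}: {msg}" for ln, msg in malformed[:5])
        raise ValueError(
            f"{len(malformed)}/{n_lines} malformed hit lines (> "
            f"{max_malformed_frac:.0%}): {preview}")
    hits = pd.DataFrame(rows, columns=list(HIT_COLUMNS))
    if len(hits):
        hits["minus_strand"] = hits["sstart"] > hits["send"]
    else:
        hits["minus_strand"] = pd.Series(dtype=bool)
    hits.attrs["malformed"] = malformed
    return hits


def filter_hits(
    hits: pd.DataFrame,
    intervals: IntervalSet,
    evalue_cutoff: float = 1e-5,
) -> tuple[set, dict]:
    """ACR transcript ids: hits with e-value <= cutoff overlapping an interval.

    Overlap requires >= 1 shared base between the subject span (strand
    normalised) and the interval on the same chromosome.  Returns the
    distinct query ids and per-interval-label hit counts.
    """
    if evalue_cutoff <= 0:
        raise ValueError("evalue_cutoff must be > 0")
    acr: set = set()
    per_interval = {iv.label: 0 for iv in intervals}
    if not len(hits):
        return acr, per_interval
    passing = hits.loc[hits["evalue"] <= evalue_cutoff]
    for row in passing.itertuples(index=False):
        lo, hi = min(row.sstart, row.send), max(row.sstart, row.send)
        for iv in intervals:
            if iv.overlaps(lo, hi, row.sseqid):
                per_interval[iv.label] += 1
                acr.add(row.qseqid)
    return acr, per_interval


@dataclass
class CandidateSet:
    """ACR transcripts and the seed subset that is also specific and/or DE."""

    acr_transcripts: set
    seed_transcripts: set
    provenance: dict = field(default_factory=dict)  # id -> set of source flags

    def to_frame(self) -> pd.DataFrame:
        rows = [(t, t in self.seed_transcripts,
                 ";".join(sorted(self.provenance.get(t, set()))))
                for t in sorted(self.acr_transcripts)]
        return pd.DataFrame(rows, columns=["transcript_id", "is_seed", "provenance"])


def build_candidates(acr_set, partition, workflow) -> CandidateSet:
    """Intersect the ACR set with specific and DE sets to get network seeds.

    ``seed_transcripts = acr_set & (union of class-specific sets | union of
    DE-called sets over all pairwise comparisons)``; provenance flags record
    every contributing source (a transcript DE in two comparisons appears
    once with both flags).
    """
    provenance: dict = {}

    def _flag(t, flag):
        provenance.setdefault(t, set()).add(flag)

    acr_set = set(acr_set)
    for cls, members in partition.specific_sets.items():
        for t in members & acr_set:
            _flag(t, f"specific:{cls}")
    from .ebde import de_called

    for pair, table in workflow.comparisons.items():
        called = de_called(table)
        for t in called & acr_set:
            _flag(t, "de:{}|{}".format(*pair))
    seeds = set(provenance)
    return CandidateSet(acr_transcripts=acr_set, seed_transcripts=seeds,
                        provenance=provenance)
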