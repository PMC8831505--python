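"""Guide counting from amplicon FASTQ and count normalization.

Because a targeted screen is a closed library of known 20-mers embedded
in a fixed cassette, alignment reduces to anchored matching: find the
3' end of the upstream flank, take the next 20 nt as the candidate
spacer, confirm the start of the tracr flank follows, then match the
spacer against the library exactly or — optionally — at Hamming
distance 1 when the rescue is unambiguous.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .library import SPACER_LEN, GuideLibrary
from .simulate import CountTable

__all__ = [
    "ExtractionPolicy",
    "SampleCounts",
    "extract_spacer",
    "count_sample",
    "count_samples",
    "cpm_normalize",
    "control_normalize",
]


@dataclass(frozen=True)
class ExtractionPolicy:
    """Anchors and mismatch allowances for spacer extraction.

    Defaults anchor on the 3' 9-mer of the upstream flank and the 5'
    6-mer of the tracr flank.
    """

    anchor_up: str = "CCTTGTTTG"
    anchor_down: str = "GTTTTA"
    anchor_mismatches: int = 0
    spacer_mismatches: int = 1

    def __post_init__(self) -> None:
        if not self.anchor_up or not self.anchor_down:
            raise ValueError("anchors must be non-empty")
        if self.anchor_mismatches < 0 or self.spacer_mismatches < 0:
            raise ValueError("mismatch allowances must be >= 0")


@dataclass
class SampleCounts:
    """Per-guide counts for one sample plus the mapping accounting.

    Invariant: counts.sum() + n_unmapped == n_total_reads.
    """

    counts: pd.Series
    n_unmapped: int
    n_total_reads: int

    def __post_init__(self) -> None:
        if int(self.counts.sum()) + self.n_unmapped != self.n_total_reads:
            raise ValueError("mapped + unmapped != total reads")


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _find_anchor(read: str, anchor: str, max_mm: int, start: int = 0) -> int:
    """Leftmost position of ``anchor`` in ``read`` at <= max_mm
    substitutions, or -1."""
    if max_mm == 0:
        return read.find(anchor, start)
    la = len(anchor)
    for i in range(start, len(read) - la + 1):
        if _hamming(read[i:i + la], anchor) <= max_mm:
            return i
    return -1


def _candidate_spacers(read_sequence: str, policy: ExtractionPolicy):
    """Yield candidate spacers at every upstream-anchor occurrence whose
    downstream anchor also checks out, left to right.  Scanning past
    anchor occurrences that fail the grammar makes extraction robust to
    chance anchor hits in flanking sequence."""
    pos = _find_anchor(read_sequence, policy.anchor_up,
                       policy.anchor_mismatches)
    while pos >= 0:
        start = pos + len(policy.anchor_up)
        end = start + SPACER_LEN
        down_end = end + len(policy.anchor_down)
        if down_end > len(read_sequence):
            return
        if _hamming(read_sequence[end:down_end],
                    policy.anchor_down) <= policy.anchor_mismatches:
            yield read_sequence[start:end]
        pos = _find_anchor(read_sequence, policy.anchor_up,
                           policy.anchor_mismatches, start=pos + 1)


def extract_spacer(read_sequence: str, policy: ExtractionPolicy) -> str | None:
    """Pull the 20-nt spacer out of one read, or None if the cassette
    grammar is not found intact."""
    return next(_candidate_spacers(read_sequence, policy), None)


def _mismatch_index(library: GuideLibrary) -> dict[str, str | None]:
    """Map each Hamming-distance-1 neighbour of a library spacer to its
    guide_id, or to None when the neighbour is ambiguous (reachable from
    two different spacers) or collides with another exact spacer."""
    exact = {g.spacer: g.guide_id for g in library.guides}
    index: dict[str, str | None] = {}
    for g in library.guides:
        s = g.spacer
        for i in range(SPACER_LEN):
            for b in "ACGT":
                if b == s[i]:
                    continue
                v = s[:i] + b + s[i + 1:]
                if v in exact:
                    continue  # exact match always wins
                if v in index and index[v] != g.guide_id:
                    index[v] = None  # ambiguous between two guides
                else:
                    index[v] = g.guide_id
    return index


def _open_maybe_gzip(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def count_sample(
    fastq_path,
    library: GuideLibrary,
    policy: ExtractionPolicy | None = None,
    search_both_strands: bool = False,
) -> SampleCounts:
    """Count library guides in one FASTQ sample.

    Extracted spacers are assigned by exact match first; with
    ``spacer_mismatches == 1`` an unmatched spacer is rescued to a
    library spacer at Hamming distance 1 only when that assignment is
    unique.  Everything else is unmapped.  Deterministic.
    """
    policy = policy or ExtractionPolicy()
    exact = {g.spacer: g.guide_id for g in library.guides}
    rescue = _mismatch_index(library) if policy.spacer_mismatches >= 1 else {}
    counts = {g.guide_id: 0 for g in library.guides}
    n_total = 0
    n_unmapped = 0
    with _open_maybe_gzip(fastq_path) as fh:
        try:
            def assign(seq: str) -> str | None:
                # try each grammar-valid candidate until one maps
                for spacer in _candidate_spacers(seq, policy):
                    guide = exact.get(spacer)
                    if guide is None and policy.spacer_mismatches >= 1:
                        guide = rescue.get(spacer)
                    if guide is not None:
                        return guide
                return None

            for _title, seq, _qual in FastqGeneralIterator(fh):
                n_total += 1
                seq = seq.upper()
                guide = assign(seq)
                if guide is None and search_both_strands:
                    guide = assign(
                        seq[::-1].translate(str.maketrans("ACGTN", "TGCAN"))
                    )
                if guide is None:
                    n_unmapped += 1
                else:
                    counts[guide] += 1
        except ValueError as e:
            raise IOError(
                f"malformed FASTQ {fastq_path!s} near record {n_total + 1}: {e}"
            ) from e
    series = pd.Series(counts, name="count").reindex(library.guide_ids)
    return SampleCounts(counts=series, n_unmapped=n_unmapped,
                        n_total_reads=n_total)


def count_samples(
    fastq_paths: dict[str, str],
    library: GuideLibrary,
    samples: pd.DataFrame,
    policy: ExtractionPolicy | None = None,
) -> tuple[CountTable, pd.DataFrame]:
    """Count a set of samples (sample_id -> FASTQ path) into a
    CountTable plus a per-sample mapping-stats frame."""
    columns = {}
    stats = []
    for sid, path in fastq_paths.items():
        sc = count_sample(path, library, policy)
        columns[sid] = sc.counts.to_numpy()
        stats.append({"sample_id": sid, "n_total_reads": sc.n_total_reads,
                      "n_mapped": int(sc.counts.sum()),
                      "n_unmapped": sc.n_unmapped})
    counts = pd.DataFrame(columns, index=pd.Index(library.guide_ids,
                                                  name="guide_id"))
    table = CountTable(counts=counts, samples=samples.loc[list(columns)])
    return table, pd.DataFrame(stats).set_index("sample_id")


def cpm_normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million mapped reads: each column rescaled to sum 1e6."""
    totals = counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(
            f"samples with zero mapped reads: {list(zero.index)}"
        )
    return counts * 1e6 / totals


def control_normalize(counts: pd.DataFrame, library: GuideLibrary) -> pd.DataFrame:
    """Median-of-controls normalization: each column scaled so the
    median control-guide count is constant (1e6 / n_guides per control
    median unit), an alternative to CPM when controls dominate depth
    differences."""
    ctrl = library.control_ids
    if not ctrl:
        raise ValueError("library has no control guides")
    med = counts.loc[ctrl].median(axis=0)
    zero = med[med == 0]
    if len(zero):
        raise ValueError(
            f"samples with zero median control count: {list(zero.index)}"
        )
    target = float(med.median())
    return counts * target / med
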