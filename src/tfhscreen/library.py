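"""sgRNA library construction, validation and serialization.

A targeted knockout library is a flat list of guides: each guide has a
unique id, a target gene symbol (or the control namespace ``CTRL`` for
non-targeting guides), and a 20-nt spacer that both programs Cas9 and
identifies the guide in amplicon sequencing.  Cloning oligos embed the
spacer between fixed mU6/tracrRNA flank sequences; the flanks double as
the anchors the read quantifier searches for.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "ARRAY_FLANK_UP",
    "ARRAY_FLANK_DOWN",
    "POOL_FLANK_UP",
    "POOL_FLANK_DOWN",
    "CONTROL_GENE",
    "GuideRecord",
    "GuideLibrary",
    "build_library",
    "assemble_array_oligo",
    "assemble_pool_oligo",
    "read_library",
    "write_library",
    "write_spacer_fasta",
]

# Fixed flank sequences for individually synthesized (array) oligos:
# partial mU6 promoter upstream, partial tracrRNA scaffold downstream.
ARRAY_FLANK_UP = "ggagaaaagccttgtttg"
ARRAY_FLANK_DOWN = "gttttagagctaggatcctagc"

# Pooled-synthesis oligos carry extended flanks for amplification.
POOL_FLANK_UP = "caattggagaaaagccttgtttg"
POOL_FLANK_DOWN = "gttttagagctaggatcctagcaagtt"

#: Gene-symbol namespace reserved for non-targeting control guides.
CONTROL_GENE = "CTRL"

SPACER_LEN = 20
_SPACER_RE = re.compile(r"^[ACGT]{20}$")
_HOMOPOLYMER_RE = re.compile(r"(A{6}|C{6}|G{6}|T{6})")


class LibraryError(ValueError):
    """Raised when a guide or library violates a structural invariant."""


def _check_spacer(spacer: str) -> str:
    if not isinstance(spacer, str) or not _SPACER_RE.match(spacer):
        raise LibraryError(
            f"spacer must be a 20-nt uppercase A/C/G/T string, got {spacer!r}"
        )
    return spacer


@dataclass(frozen=True)
class GuideRecord:
    """One sgRNA: id, target gene, 20-nt spacer, control flag."""

    guide_id: str
    gene_symbol: str
    spacer: str
    is_control: bool = False

    def __post_init__(self) -> None:
        _check_spacer(self.spacer)
        if self.is_control != (self.gene_symbol == CONTROL_GENE):
            raise LibraryError(
                f"guide {self.guide_id}: is_control={self.is_control} but "
                f"gene_symbol={self.gene_symbol!r} (controls must use "
                f"{CONTROL_GENE!r} and vice versa)"
            )


@dataclass
class GuideLibrary:
    """Ordered collection of guides with a per-gene design multiplicity."""

    guides: list[GuideRecord]
    guides_per_gene: int
    name: str = "library"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.guides_per_gene < 1:
            raise LibraryError("guides_per_gene must be >= 1")
        ids = [g.guide_id for g in self.guides]
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise LibraryError(f"duplicate guide_id {dup!r}")
        spacers = [g.spacer for g in self.guides]
        if len(set(spacers)) != len(spacers):
            raise LibraryError("duplicate spacer in library")
        per_gene: dict[str, int] = {}
        for g in self.guides:
            if not g.is_control:
                per_gene[g.gene_symbol] = per_gene.get(g.gene_symbol, 0) + 1
        bad = {s: n for s, n in per_gene.items() if n != self.guides_per_gene}
        if bad:
            raise LibraryError(
                f"genes without exactly {self.guides_per_gene} guides: {bad}"
            )

    def __len__(self) -> int:
        return len(self.guides)

    def __iter__(self):
        return iter(self.guides)

    @property
    def guide_ids(self) -> list[str]:
        return [g.guide_id for g in self.guides]

    @property
    def genes(self) -> list[str]:
        """Targeted gene symbols in first-appearance order (controls excluded)."""
        seen: dict[str, None] = {}
        for g in self.guides:
            if not g.is_control:
                seen.setdefault(g.gene_symbol, None)
        return list(seen)

    @property
    def control_ids(self) -> list[str]:
        return [g.guide_id for g in self.guides if g.is_control]

    @property
    def n_targeting(self) -> int:
        return sum(not g.is_control for g in self.guides)

    def gene_of(self) -> pd.Series:
        """guide_id -> gene_symbol mapping as a Series."""
        return pd.Series(
            {g.guide_id: g.gene_symbol for g in self.guides}, name="gene_symbol"
        )

    def spacer_of(self) -> dict[str, str]:
        return {g.guide_id: g.spacer for g in self.guides}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "guide_id": [g.guide_id for g in self.guides],
                "gene_symbol": [g.gene_symbol for g in self.guides],
                "spacer": [g.spacer for g in self.guides],
                "is_control": [g.is_control for g in self.guides],
            }
        )


def _random_spacer(rng: np.random.Generator) -> str:
    return "".join(rng.choice(list("ACGT"), size=SPACER_LEN))


def build_library(
    gene_symbols: list[str],
    guides_per_gene: int,
    n_controls: int = 0,
    seed: int = 0,
    name: str = "library",
) -> GuideLibrary:
    """Build a synthetic targeted library.

    Spacers are uniform random 20-mers, rejecting duplicates and
    homopolymer runs of 6 or more.  Deterministic for a fixed ``seed``.

    Parameters
    ----------
    gene_symbols : unique, non-empty list of target genes.
    guides_per_gene : guides designed per gene (the screens used 5 or 4).
    n_controls : number of non-targeting control guides appended.
    """
    if not gene_symbols:
        raise LibraryError("gene_symbols must be non-empty")
    if len(set(gene_symbols)) != len(gene_symbols):
        raise LibraryError("duplicate gene symbols")
    if guides_per_gene < 1:
        raise LibraryError("guides_per_gene must be >= 1")
    if CONTROL_GENE in gene_symbols:
        raise LibraryError(f"{CONTROL_GENE!r} is reserved for control guides")
    n_total = len(gene_symbols) * guides_per_gene + n_controls
    if n_total > 4**SPACER_LEN // 2:  # practical uniqueness bound
        raise LibraryError("requested library exceeds spacer-space bound")

    rng = np.random.default_rng(seed)
    spacers: set[str] = set()
    out: list[str] = []
    attempts = 0
    while len(out) < n_total:
        s = _random_spacer(rng)
        attempts += 1
        if attempts > 100 * n_total + 1000:
            raise LibraryError("could not generate enough unique spacers")
        if s in spacers or _HOMOPOLYMER_RE.search(s):
            continue
        spacers.add(s)
        out.append(s)

    guides: list[GuideRecord] = []
    it = iter(out)
    for gene in gene_symbols:
        for j in range(1, guides_per_gene + 1):
            guides.append(
                GuideRecord(f"{gene}_sg{j}", gene, next(it), is_control=False)
            )
    for j in range(1, n_controls + 1):
        guides.append(
            GuideRecord(f"{CONTROL_GENE}_sg{j}", CONTROL_GENE, next(it), is_control=True)
        )
    return GuideLibrary(guides=guides, guides_per_gene=guides_per_gene, name=name)


def assemble_array_oligo(spacer: str) -> str:
    """Cloning oligo for individually synthesized guides.

    Lowercase flanks, uppercase spacer; total length 60 nt.
    """
    return ARRAY_FLANK_UP + _check_spacer(spacer) + ARRAY_FLANK_DOWN


def assemble_pool_oligo(spacer: str) -> str:
    """Cloning oligo for pooled synthesis (extended flanks); length 70 nt."""
    return POOL_FLANK_UP + _check_spacer(spacer) + POOL_FLANK_DOWN


_CSV_COLUMNS = ["guide_id", "gene_symbol", "spacer", "is_control"]


def write_library(lib: GuideLibrary, path) -> None:
    """Serialize the library as CSV (guide_id, gene_symbol, spacer, is_control)."""
    lib.to_frame().to_csv(path, index=False)


def read_library(path, guides_per_gene: int | None = None,
                 name: str | None = None) -> GuideLibrary:
    """Read a library CSV; infers guides_per_gene from the modal gene size
    when not given.  Raises :class:`LibraryError` naming the offending row.
    """
    df = pd.read_csv(path, dtype={"guide_id": str, "gene_symbol": str,
                                  "spacer": str})
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise LibraryError(f"library CSV missing columns: {missing}")
    guides = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            guides.append(
                GuideRecord(
                    guide_id=row.guide_id,
                    gene_symbol=row.gene_symbol,
                    spacer=row.spacer,
                    is_control=bool(row.is_control),
                )
            )
        except LibraryError as e:
            raise LibraryError(f"row {i + 2}: {e}") from e  # +2: header + 1-based
    if guides_per_gene is None:
        sizes = pd.Series(
            [g.gene_symbol for g in guides if not g.is_control]
        ).value_counts()
        guides_per_gene = int(sizes.mode().iloc[0]) if len(sizes) else 1
    if name is None:
        name = str(getattr(path, "stem", path))
    return GuideLibrary(guides=guides, guides_per_gene=guides_per_gene, name=name)


def write_spacer_fasta(lib: GuideLibrary, path) -> None:
    """Export spacers as FASTA, one record per guide (id = guide_id)."""
    records = (
        SeqRecord(Seq(g.spacer), id=g.guide_id, description=g.gene_symbol)
        for g in lib.guides
    )
    SeqIO.write(records, path, "fasta")
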