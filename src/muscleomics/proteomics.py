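"""Spectral-count label-free differential proteomics via the Rsc statistic.

The abundance of a protein in a pooled one-lane-per-group design is proxied
by its spectral count (SpC): the number of MS/MS spectra assigned to it.
Between two groups the log2 abundance ratio is estimated by

    Rsc = log2((n2 + f) / (n1 + f)) + log2((t1 - n1 + f) / (t2 - n2 + f))

where ``n1``/``n2`` are the protein's counts in the two groups, ``t1``/``t2``
the total assigned spectra per group, and ``f`` an additive correction
(default 0.5) that keeps the statistic finite when a protein is absent from
one lane.  The second term corrects for unequal lane depth.  The contrast is
oriented so that a positive Rsc means higher abundance in the *focus*
(numerator) group: the formula's ``n2`` slot holds the focus group's count.

Proteins with |Rsc| at or beyond a threshold (default 1.40, i.e. ~2.6-fold)
are called differentially represented.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "IdentificationRecord",
    "SpectralCountEntry",
    "RscResult",
    "DuplicateRecordError",
    "filter_identifications",
    "aggregate_counts",
    "compute_rsc",
    "classify_differential",
    "run_proteomics",
    "SpectralCountContrast",
    "RscResults",
    "load_reference_rsc_table",
]

IDENTIFICATION_COLUMNS = [
    "accession",
    "description",
    "gene",
    "group",
    "n_peptides",
    "min_peptide_score",
    "spectral_count",
]


class DuplicateRecordError(ValueError):
    """Raised when one accession carries two rows for the same group."""


@dataclass(frozen=True)
class IdentificationRecord:
    """One protein's identification evidence and SpC within one group."""

    accession: str
    description: str
    gene: str
    group: str
    n_peptides: int
    min_peptide_score: float
    spectral_count: int

    def __post_init__(self) -> None:
        if self.n_peptides < 0:
            raise ValueError(f"{self.accession}: n_peptides < 0")
        if self.spectral_count < 0:
            raise ValueError(f"{self.accession}: spectral_count < 0")


@dataclass(frozen=True)
class SpectralCountEntry:
    """Per-protein pooled counts plus the shared lane totals.

    ``n1``/``t1`` belong to the reference (denominator) lane and
    ``n2``/``t2`` to the focus (numerator) lane of the contrast.
    """

    accession: str
    n1: int
    n2: int
    t1: int
    t2: int

    def __post_init__(self) -> None:
        if not (0 <= self.n1 <= self.t1):
            raise ValueError(f"{self.accession}: need 0 <= n1 <= t1, got n1={self.n1}, t1={self.t1}")
        if not (0 <= self.n2 <= self.t2):
            raise ValueError(f"{self.accession}: need 0 <= n2 <= t2, got n2={self.n2}, t2={self.t2}")

    def swapped(self) -> "SpectralCountEntry":
        """The same entry with the two lanes exchanged."""
        return SpectralCountEntry(self.accession, self.n2, self.n1, self.t2, self.t1)


@dataclass(frozen=True)
class RscResult:
    accession: str
    rsc: float
    diff_class: str  # over | under | unchanged


def filter_identifications(
    records: Sequence[IdentificationRecord],
    min_peptides: int = 2,
    min_score: float = 19.0,
) -> list[IdentificationRecord]:
    """Apply the identification acceptance rules.

    A protein row is retained when it has at least ``min_peptides`` assigned
    peptides AND its weakest counted peptide scores strictly above
    ``min_score``.  Order is preserved.
    """
    kept = [
        r
        for r in records
        if r.n_peptides >= min_peptides and r.min_peptide_score > min_score
    ]
    logger.info(
        "identification filter (n_peptides >= %d, score > %g): %d -> %d records",
        min_peptides, min_score, len(records), len(kept),
    )
    return kept


def aggregate_counts(
    records: Sequence[IdentificationRecord],
    sample1: str,
    sample2: str,
) -> list[SpectralCountEntry]:
    """Collapse per-group identification rows into per-protein count entries.

    ``sample1`` fills the ``n1`` (reference) slot and ``sample2`` the ``n2``
    (focus) slot.  A protein seen in only one group gets count 0 in the
    other; the lane totals t1, t2 are the sums over all retained proteins.
    """
    if sample1 == sample2:
        raise ValueError("sample1 and sample2 must differ")
    counts: dict[str, dict[str, int]] = {}
    order: list[str] = []
    for r in records:
        if r.group not in (sample1, sample2):
            raise ValueError(f"{r.accession}: unknown group label {r.group!r}")
        slot = counts.setdefault(r.accession, {})
        if r.group in slot:
            raise DuplicateRecordError(
                f"duplicate record for accession {r.accession!r} in group {r.group!r}"
            )
        slot[r.group] = r.spectral_count
        if r.accession not in order:
            order.append(r.accession)
    t1 = sum(c.get(sample1, 0) for c in counts.values())
    t2 = sum(c.get(sample2, 0) for c in counts.values())
    return [
        SpectralCountEntry(acc, counts[acc].get(sample1, 0), counts[acc].get(sample2, 0), t1, t2)
        for acc in order
    ]


def compute_rsc(entry: SpectralCountEntry, f: float = 0.5) -> float:
    """Rsc log2 abundance ratio for one protein.

    Positive values indicate higher abundance in the focus lane (the one
    whose count sits in ``n2``).  Finite for every valid entry as long as
    f > 0.
    """
    if f <= 0:
        raise ValueError("correction factor f must be > 0")
    n1, n2, t1, t2 = entry.n1, entry.n2, entry.t1, entry.t2
    if t1 < n1 or t2 < n2:
        raise ValueError(f"{entry.accession}: lane total smaller than protein count")
    return math.log2((n2 + f) / (n1 + f)) + math.log2((t1 - n1 + f) / (t2 - n2 + f))


def classify_differential(
    results: Iterable[tuple[str, float]],
    threshold: float = 1.40,
) -> tuple[list[RscResult], dict[str, int]]:
    """Partition proteins into over / under / unchanged at |Rsc| >= threshold.

    Boundary values count as differential (>= / <=).  Returns the per-protein
    classification and a summary dict with n_over, n_under,
    n_total_differential.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    out: list[RscResult] = []
    for accession, rsc in results:
        if rsc >= threshold:
            cls = "over"
        elif rsc <= -threshold:
            cls = "under"
        else:
            cls = "unchanged"
        out.append(RscResult(accession, rsc, cls))
    n_over = sum(1 for r in out if r.diff_class == "over")
    n_under = sum(1 for r in out if r.diff_class == "under")
    summary = {
        "n_over": n_over,
        "n_under": n_under,
        "n_unchanged": len(out) - n_over - n_under,
        "n_total_differential": n_over + n_under,
    }
    return out, summary


# ---------------------------------------------------------------------------
# Model / Results presentation


class SpectralCountContrast:
    """Two-group spectral-count contrast model.

    Built from a tidy identification table (one row per protein per group);
    ``fit`` runs the filter -> aggregate -> Rsc -> classify chain and returns
    an :class:`RscResults`.

    Parameters
    ----------
    records
        Identification rows for both groups.
    focus, reference
        Group labels; positive Rsc means higher in ``focus``.
    """

    def __init__(
        self,
        records: Sequence[IdentificationRecord],
        focus: str,
        reference: str,
    ) -> None:
        if focus == reference:
            raise ValueError("focus and reference groups must differ")
        self.records = list(records)
        self.focus = focus
        self.reference = reference

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, focus: str, reference: str) -> "SpectralCountContrast":
        missing = [c for c in IDENTIFICATION_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"identification table missing columns: {missing}")
        records = [
            IdentificationRecord(
                accession=str(row.accession),
                description=str(row.description),
                gene=str(row.gene),
                group=str(row.group),
                n_peptides=int(row.n_peptides),
                min_peptide_score=float(row.min_peptide_score),
                spectral_count=int(row.spectral_count),
            )
            for row in df.itertuples(index=False)
        ]
        return cls(records, focus=focus, reference=reference)

    @classmethod
    def from_tsv(cls, path: str | Path, focus: str, reference: str) -> "SpectralCountContrast":
        return cls.from_dataframe(pd.read_csv(path, sep="\t"), focus=focus, reference=reference)

    def fit(
        self,
        f: float = 0.5,
        rsc_threshold: float = 1.40,
        min_peptides: int = 2,
        min_score: float = 19.0,
    ) -> "RscResults":
        kept = filter_identifications(self.records, min_peptides, min_score)
        # the formula's n2 slot is the focus group's count
        entries = aggregate_counts(kept, sample1=self.reference, sample2=self.focus)
        rsc = {e.accession: compute_rsc(e, f=f) for e in entries}
        classified, summary = classify_differential(rsc.items(), threshold=rsc_threshold)
        genes = {r.accession: r.gene for r in kept}
        return RscResults(
            model=self,
            entries=entries,
            classified=classified,
            summary=summary,
            genes=genes,
            params={
                "f": f,
                "rsc_threshold": rsc_threshold,
                "min_peptides": min_peptides,
                "min_score": min_score,
            },
        )


@dataclass
class RscResults:
    """Fitted spectral-count contrast: per-protein Rsc and classification."""

    model: SpectralCountContrast
    entries: list[SpectralCountEntry]
    classified: list[RscResult]
    summary: dict[str, int]
    genes: dict[str, str]
    params: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        cls = {r.accession: r for r in self.classified}
        rows = [
            {
                "accession": e.accession,
                "gene": self.genes.get(e.accession, ""),
                "n1": e.n1,
                "n2": e.n2,
                "t1": e.t1,
                "t2": e.t2,
                "rsc": cls[e.accession].rsc,
                "diff_class": cls[e.accession].diff_class,
            }
            for e in self.entries
        ]
        return pd.DataFrame(
            rows, columns=["accession", "gene", "n1", "n2", "t1", "t2", "rsc", "diff_class"]
        )

    @property
    def over(self) -> list[str]:
        return [r.accession for r in self.classified if r.diff_class == "over"]

    @property
    def under(self) -> list[str]:
        return [r.accession for r in self.classified if r.diff_class == "under"]

    def summary_text(self) -> str:
        p = self.params
        lines = [
            f"Spectral-count contrast: {self.model.focus} (focus) vs {self.model.reference} (reference)",
            f"  proteins quantified : {len(self.entries)}",
            f"  f = {p['f']}, |Rsc| threshold = {p['rsc_threshold']}, "
            f"filter: peptides >= {p['min_peptides']}, score > {p['min_score']}",
            f"  over  (Rsc >= {p['rsc_threshold']})  : {self.summary['n_over']}",
            f"  under (Rsc <= -{p['rsc_threshold']}) : {self.summary['n_under']}",
            f"  unchanged                 : {self.summary['n_unchanged']}",
        ]
        return "\n".join(lines)

    def write(self, out_dir: str | Path, stem: str = "proteomics") -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(out / f"{stem}_results.tsv", sep="\t", index=False)
        (out / f"{stem}_summary.json").write_text(json.dumps(self.summary, indent=2) + "\n")


def run_proteomics(
    identifications_path: str | Path,
    focus: str,
    reference: str,
    out_dir: str | Path | None = None,
    f: float = 0.5,
    rsc_threshold: float = 1.40,
    min_peptides: int = 2,
    min_score: float = 19.0,
) -> RscResults:
    """Read an identification TSV and run the full proteomics chain."""
    df = pd.read_csv(identifications_path, sep="\t")
    if df.empty:
        logger.info("empty identification table: %s", identifications_path)
        model = SpectralCountContrast([], focus=focus, reference=reference)
        results = model.fit(f, rsc_threshold, min_peptides, min_score)
    else:
        model = SpectralCountContrast.from_dataframe(df, focus=focus, reference=reference)
        results = model.fit(f, rsc_threshold, min_peptides, min_score)
    logger.info(results.summary_text())
    if out_dir is not None:
        results.write(out_dir)
    return results


def load_reference_rsc_table() -> pd.DataFrame:
    """Packaged table of published per-protein Rsc values (accession, gene, rsc).

    Differential proteins from a lifelong-football muscle study: the printed
    Rsc of each protein called over- or underexpressed at |Rsc| >= 1.40.
    """
    ref = resources.files("muscleomics.fixtures") / "table2_table3_rsc.tsv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")
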