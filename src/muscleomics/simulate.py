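"""Synthetic data with planted ground truth for every pipeline stage.

Three generators mirror the study designs the pipeline targets:

* a pooled two-group spectral-count proteome — one pooled lane per group,
  counts drawn multinomially so each lane total is hit exactly, with a
  configurable fraction of proteins planted up or down at a fixed log2 fold
  change;
* a two-group targeted metabolite panel (amino acids + acylcarnitines,
  n per group configurable) with log-normal measurement noise and planted
  multiplicative effects;
* random annotation term sets in GMT form, optionally with one term whose
  members are drawn preferentially from a designated protein subset, so the
  enrichment stage has a known positive.

All draws flow from a single ``numpy.random.Generator`` seeded from the
config, in a fixed stream order (baselines first, then per-group counts /
per-sample noise), so fixtures are reproducible across calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .enrichment import AnnotationSet
from .metabolomics import MetabolitePanel
from .proteomics import IdentificationRecord, SpectralCountEntry

__all__ = [
    "ProteomeSimConfig",
    "MetaboSimConfig",
    "DEFAULT_METABOLITE_PANEL",
    "DegenerateConfigError",
    "simulate_spectral_counts",
    "simulate_identifications",
    "simulate_metabolite_panel",
    "simulate_annotation_sets",
]


class DegenerateConfigError(ValueError):
    """Configuration that would produce a meaningless simulation."""


# A 50-metabolite amino-acid / acylcarnitine panel of the kind measured by
# flow-injection MS/MS newborn-screening style assays.
DEFAULT_METABOLITE_PANEL: tuple[str, ...] = (
    # amino acids
    "Ala", "Arg", "Asp", "Cit", "Glu", "Gly", "Leu", "Met", "Orn", "Phe",
    "Pro", "Ser", "Thr", "Trp", "Tyr", "Val",
    # free carnitine and short-chain acylcarnitines
    "C0", "C2", "C3", "C4", "C5", "C5:1", "C5OH", "C5DC", "C4DC",
    # medium-chain
    "C6", "C6DC", "C8", "C8:1", "C8DC", "C10", "C10:1", "C10:2", "C12",
    "C12:1", "C12OH",
    # long-chain
    "C14", "C14:1", "C14:2", "C14OH", "C16", "C16:1", "C16OH", "C16:1OH",
    "C18", "C18:1", "C18:2", "C18OH", "C18:1OH", "C18:2OH",
)
assert len(DEFAULT_METABOLITE_PANEL) == 50


@dataclass(frozen=True)
class ProteomeSimConfig:
    """Pooled two-group spectral-count design with planted effects.

    ``planted_log2fc`` is applied to group A: up-proteins are 2**fc more
    abundant in A, down-proteins 2**fc less.  ``baseline_dispersion`` is the
    sd (natural-log scale) of the per-protein baseline abundance, giving the
    heavy-tailed count distribution real proteomes show.
    """

    n_proteins: int = 500
    frac_up: float = 0.1
    frac_down: float = 0.1
    planted_log2fc: float = 2.0
    total_spectra_per_group: int = 20_000
    baseline_dispersion: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins <= 0:
            raise ValueError("n_proteins must be > 0")
        if self.total_spectra_per_group <= 0:
            raise ValueError("total_spectra_per_group must be > 0")
        if not (0 <= self.frac_up <= 1 and 0 <= self.frac_down <= 1):
            raise ValueError("fractions must lie in [0, 1]")
        if self.frac_up + self.frac_down > 1:
            raise ValueError("frac_up + frac_down must be <= 1")
        if self.planted_log2fc < 0:
            raise ValueError("planted_log2fc must be >= 0")
        if self.baseline_dispersion <= 0:
            raise ValueError("baseline_dispersion must be > 0")
        if self.total_spectra_per_group < self.n_proteins:
            raise DegenerateConfigError(
                "expected count per protein < 1: increase total_spectra_per_group "
                "or reduce n_proteins"
            )


def simulate_spectral_counts(
    cfg: ProteomeSimConfig,
) -> tuple[list[SpectralCountEntry], dict[str, str]]:
    """Simulate pooled per-group spectral counts with planted effects.

    Returns entries with ``n2`` = group A (focus) and ``n1`` = group B
    (reference) counts — positive Rsc should recover planted "up" proteins —
    plus the ground-truth class (``up`` / ``down`` / ``null``) per accession.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_proteins
    accessions = [f"P{i:05d}" for i in range(n)]
    n_up = round(cfg.frac_up * n)
    n_down = round(cfg.frac_down * n)
    truth = {}
    for i, acc in enumerate(accessions):
        truth[acc] = "up" if i < n_up else ("down" if i < n_up + n_down else "null")

    base = rng.lognormal(mean=0.0, sigma=cfg.baseline_dispersion, size=n)
    mult = np.ones(n)
    mult[:n_up] = 2.0**cfg.planted_log2fc
    mult[n_up : n_up + n_down] = 2.0**-cfg.planted_log2fc
    abund_a = base * mult
    abund_b = base
    counts_a = rng.multinomial(cfg.total_spectra_per_group, abund_a / abund_a.sum())
    counts_b = rng.multinomial(cfg.total_spectra_per_group, abund_b / abund_b.sum())
    t = cfg.total_spectra_per_group
    entries = [
        SpectralCountEntry(acc, n1=int(cb), n2=int(ca), t1=t, t2=t)
        for acc, ca, cb in zip(accessions, counts_a, counts_b)
    ]
    return entries, truth


def simulate_identifications(
    cfg: ProteomeSimConfig,
    group_a: str = "VPG",
    group_b: str = "CG",
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Identification-table view of a simulated proteome.

    Emits one row per protein per group in the tidy format the proteomics
    stage reads (peptide evidence passes the default acceptance filter), so
    end-to-end runs can start from a TSV on disk.
    """
    entries, truth = simulate_spectral_counts(cfg)
    rng = np.random.default_rng(cfg.seed + 1)
    rows = []
    for e in entries:
        n_pep = int(rng.integers(2, 12))
        score = float(rng.uniform(20.0, 120.0))
        for group, count in ((group_a, e.n2), (group_b, e.n1)):
            rows.append(
                {
                    "accession": e.accession,
                    "description": f"synthetic protein {e.accession}",
                    "gene": f"GENE{e.accession[1:]}",
                    "group": group,
                    "n_peptides": n_pep,
                    "min_peptide_score": round(score, 1),
                    "spectral_count": count,
                }
            )
    return pd.DataFrame(rows), truth


@dataclass(frozen=True)
class MetaboSimConfig:
    """Two-group targeted metabolite panel with planted fold changes.

    ``planted_effects`` maps metabolite -> log2 fold change of group A over
    group B.  ``cv_noise`` is the log-normal coefficient of variation of the
    measurement noise around each group mean.
    """

    metabolite_names: tuple[str, ...] = DEFAULT_METABOLITE_PANEL
    n_per_group: int = 9
    planted_effects: Mapping[str, float] = field(default_factory=dict)
    cv_noise: float = 0.2
    seed: int = 0
    group_a: str = "VPG"
    group_b: str = "CG"

    def __post_init__(self) -> None:
        if self.n_per_group < 3:
            raise ValueError("n_per_group must be >= 3")
        if self.cv_noise <= 0:
            raise ValueError("cv_noise must be > 0")
        unknown = [m for m in self.planted_effects if m not in self.metabolite_names]
        if unknown:
            raise ValueError(f"planted_effects for unknown metabolites: {unknown}")


def simulate_metabolite_panel(
    cfg: MetaboSimConfig,
) -> tuple[MetabolitePanel, dict[str, float]]:
    """Simulate a metabolite x sample panel; returns (panel, planted truth).

    Per-metabolite baselines are log-normal (median 1, sd 1 on the natural
    log scale, i.e. concentrations spread over a few orders of magnitude, as
    AA/AC panels do); every sample value is the group mean times log-normal
    noise of coefficient of variation ``cv_noise``.  All values are strictly
    positive by construction.
    """
    rng = np.random.default_rng(cfg.seed)
    mets = list(cfg.metabolite_names)
    baselines = rng.lognormal(mean=0.0, sigma=1.0, size=len(mets))
    sigma = float(np.sqrt(np.log1p(cfg.cv_noise**2)))  # ln-sd for the given CV
    samples = [f"{cfg.group_a}{i+1}" for i in range(cfg.n_per_group)] + [
        f"{cfg.group_b}{i+1}" for i in range(cfg.n_per_group)
    ]
    groups = pd.Series(
        [cfg.group_a] * cfg.n_per_group + [cfg.group_b] * cfg.n_per_group, index=samples
    )
    data = np.empty((len(mets), len(samples)))
    for i, met in enumerate(mets):
        mean_b = baselines[i]
        mean_a = mean_b * 2.0 ** cfg.planted_effects.get(met, 0.0)
        noise = rng.lognormal(mean=-(sigma**2) / 2, sigma=sigma, size=len(samples))
        means = np.array([mean_a] * cfg.n_per_group + [mean_b] * cfg.n_per_group)
        data[i] = means * noise
    panel = MetabolitePanel(pd.DataFrame(data, index=mets, columns=samples), groups)
    return panel, dict(cfg.planted_effects)


def simulate_annotation_sets(
    n_terms: int,
    proteins: Sequence[str],
    planted_term: tuple[str, Sequence[str]] | None = None,
    seed: int = 0,
    term_size_range: tuple[int, int] = (5, 40),
    planted_in_subset_prob: float = 0.9,
) -> list[AnnotationSet]:
    """Random annotation sets plus an optionally planted enriched term.

    Each of the ``n_terms`` random terms draws a uniform-size member sample
    from ``proteins``.  ``planted_term`` is a (term_id, subset) pair: its
    members are drawn preferentially (probability ``planted_in_subset_prob``
    per member) from the subset, giving a term genuinely over-represented in
    any query resembling the subset.
    """
    if n_terms > 0 and not proteins:
        raise ValueError("proteins must be non-empty")
    if planted_term is not None and not list(planted_term[1]):
        raise ValueError("planted subset is empty")
    rng = np.random.default_rng(seed)
    proteins = list(proteins)
    sets: list[AnnotationSet] = []
    lo, hi = term_size_range
    hi = min(hi, len(proteins)) if proteins else hi
    lo = min(lo, hi)
    for i in range(n_terms):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(proteins, size=size, replace=False)
        sets.append(
            AnnotationSet(f"TERM{i:04d}", f"random term {i}", frozenset(map(str, members)))
        )
    if planted_term is not None:
        term_id, subset = planted_term
        subset = list(dict.fromkeys(subset))
        if not subset:
            raise ValueError("planted subset is empty")
        other = [p for p in proteins if p not in set(subset)]
        size = max(2, min(len(subset), int(rng.integers(lo, hi + 1))))
        members: list[str] = []
        for _ in range(size):
            pool = subset if (rng.random() < planted_in_subset_prob or not other) else other
            pick = str(rng.choice([p for p in pool if p not in members] or pool))
            if pick not in members:
                members.append(pick)
        sets.append(AnnotationSet(term_id, "planted enriched term", frozenset(members)))
    return sets
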