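"""The two-sigma statistical core.

A candidate genus is judged against the empirical distribution of
sister-clade divergences among the *established* genera of the same higher
taxon.  Each sister comparison contributes one observation — the arithmetic
mean of all cross-clade species-pair K2P distances — and the collection of
those comparison means defines a reference distribution with mean ``mu`` and
sample standard deviation ``sigma``.  A focal divergence value is then
banded:

    value <  mu - 2*sigma            REJECT_GENUS      (rank not warranted)
    [mu - 2*sigma, mu - sigma)       GENUS_WEAK_LOW    (acceptable, weak)
    [mu - sigma,  mu + sigma]        GENUS_SUPPORTED   (well supported)
    (mu + sigma,  mu + 2*sigma]      GENUS_HIGH        (acceptable, high)
    value >  mu + 2*sigma            HIGHER_CATEGORY   (tribe/subfamily-level)

Boundary values stay on the genus side: only strictly beyond two sigma is a
candidate rejected or elevated.  Everything from GENUS_WEAK_LOW through
GENUS_HIGH *qualifies for genus rank*; the outer two bands do not.

Normality of the comparison means is checked with a Shapiro-Wilk test; a
rejection does not halt the pipeline but is surfaced prominently, since the
band interpretation leans on an approximately normal reference distribution.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
from scipy import stats as sp_stats

from .alignments import TaxonTable
from .errors import (
    DegenerateDistributionError,
    EmptyComparisonError,
    InsufficientDataError,
    MonophylyError,
)
from .k2p import DistanceMatrix
from .sisters import SisterComparison, fill

logger = logging.getLogger("genusrank")


# ---------------------------------------------------------------------------
# per-comparison statistics

def comparison_stats(
    cmp: SisterComparison, D: DistanceMatrix, ddof: int = 1
) -> SisterComparison:
    """Fill a comparison's cross-pair distances, mean and SD from a matrix.

    Undefined (saturated) pairs are dropped with a warning; zero defined
    pairs is an error.  ``sd`` is None when exactly one pair remains.
    ``ddof=1`` gives the sample SD (default); 0 the population SD.
    """
    dists = []
    n_dropped = 0
    for a, b in cmp.species_pairs:
        d = D.get(a, b)
        if math.isnan(d):
            n_dropped += 1
        else:
            dists.append(d)
    if n_dropped:
        logger.warning(
            "comparison %s: %d undefined pair(s) dropped", cmp.label, n_dropped
        )
    if not dists:
        raise EmptyComparisonError(f"comparison {cmp.label}: no defined distances")
    arr = np.asarray(dists, dtype=float)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=ddof)) if arr.size > 1 else None
    return fill(cmp, pair_distances=tuple(dists), mean=mean, sd=sd)


# ---------------------------------------------------------------------------
# the aggregate distribution

def shapiro_wilk(values: Sequence[float]) -> tuple[float, float]:
    """Shapiro-Wilk composite normality test: returns (W, p).

    Requires n >= 3 and non-degenerate (not all-equal) input; delegates to
    scipy's vetted routine.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 3:
        raise InsufficientDataError("Shapiro-Wilk needs at least 3 observations")
    if np.ptp(arr) == 0.0:
        raise DegenerateDistributionError("Shapiro-Wilk undefined for constant input")
    res = sp_stats.shapiro(arr)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class SigmaDistribution:
    """The reference distribution of sister-comparison means.

    ``mu``/``sigma`` are the mean and sample SD of the comparison means (one
    datum per comparison, not per species pair).  ``shapiro_W``/``shapiro_p``
    are None when fewer than 3 means are available or the means are constant.
    """

    comparison_means: tuple
    mu: float
    sigma: float
    n: int
    shapiro_W: float | None = None
    shapiro_p: float | None = None

    @property
    def band_edges(self) -> dict[str, float]:
        """Edges mu-2s, mu-s, mu+s, mu+2s (percent, full precision)."""
        return {
            "lower_2sigma": self.mu - 2.0 * self.sigma,
            "lower_1sigma": self.mu - self.sigma,
            "upper_1sigma": self.mu + self.sigma,
            "upper_2sigma": self.mu + 2.0 * self.sigma,
        }

    @classmethod
    def from_moments(cls, mu: float, sigma: float, n: int = 0) -> "SigmaDistribution":
        """Build a distribution snapshot from already-published moments,
        e.g. to classify against a reported aggregate."""
        return cls(comparison_means=(), mu=float(mu), sigma=float(sigma), n=n)


def aggregate_distribution(cmps: Sequence[SisterComparison]) -> SigmaDistribution:
    """Aggregate filled comparisons into the reference distribution.

    Each comparison contributes its mean as a single observation; sigma uses
    the sample (n-1) denominator.  The Shapiro-Wilk test runs when
    3 <= n <= 5000 and the means are not all equal.
    """
    means = [c.mean for c in cmps if c.mean is not None]
    if len(means) < 2:
        raise InsufficientDataError(
            f"need >= 2 comparisons with defined means, got {len(means)}"
        )
    arr = np.asarray(means, dtype=float)
    mu = float(arr.mean())
    sigma = float(arr.std(ddof=1))
    W = p = None
    if 3 <= arr.size <= 5000:
        if np.ptp(arr) == 0.0:
            logger.warning(
                "degenerate distribution: all %d comparison means equal; "
                "Shapiro-Wilk undefined",
                arr.size,
            )
        else:
            W, p = shapiro_wilk(arr)
            if p <= 0.05:
                logger.warning(
                    "Shapiro-Wilk rejects normality of comparison means "
                    "(W=%.4f, p=%.4g); band interpretation is weakened",
                    W,
                    p,
                )
    return SigmaDistribution(
        comparison_means=tuple(float(m) for m in arr),
        mu=mu,
        sigma=sigma,
        n=int(arr.size),
        shapiro_W=W,
        shapiro_p=p,
    )


# ---------------------------------------------------------------------------
# classification

class Band(Enum):
    REJECT_GENUS = "REJECT_GENUS"
    GENUS_WEAK_LOW = "GENUS_WEAK_LOW"
    GENUS_SUPPORTED = "GENUS_SUPPORTED"
    GENUS_HIGH = "GENUS_HIGH"
    HIGHER_CATEGORY = "HIGHER_CATEGORY"


@dataclass(frozen=True)
class RankVerdict:
    """Band classification of one focal divergence value."""

    band: Band
    focal_value: float
    distribution: SigmaDistribution

    @property
    def supports_genus_rank(self) -> bool:
        """True when the value lies within the two-sigma band, i.e. genus
        rank is an acceptable decision (weakly or strongly supported)."""
        return self.band not in (Band.REJECT_GENUS, Band.HIGHER_CATEGORY)


def classify(value: float, dist: SigmaDistribution) -> RankVerdict:
    """Band a focal divergence against the reference distribution.

    Boundary values fall toward the genus-supported side (both two-sigma
    edges, and both one-sigma edges, are included in the inner band they
    touch).
    """
    if not (dist.sigma > 0.0):
        raise DegenerateDistributionError(
            "cannot classify against a zero-spread distribution"
        )
    mu, s = dist.mu, dist.sigma
    if value < mu - 2.0 * s:
        band = Band.REJECT_GENUS
    elif value < mu - s:
        band = Band.GENUS_WEAK_LOW
    elif value <= mu + s:
        band = Band.GENUS_SUPPORTED
    elif value <= mu + 2.0 * s:
        band = Band.GENUS_HIGH
    else:
        band = Band.HIGHER_CATEGORY
    return RankVerdict(band=band, focal_value=float(value), distribution=dist)


# ---------------------------------------------------------------------------
# within-genus profiles

@dataclass(frozen=True)
class GenusProfile:
    """Mean/SD of K2P distances over all within-genus species pairs
    (defined only for genera with at least two sequenced species)."""

    genus: str
    n_species: int
    mean_within: float
    sd_within: float | None


def within_genus_profiles(
    D: DistanceMatrix, table: TaxonTable, ddof: int = 1
) -> tuple[list[GenusProfile], dict]:
    """One profile per genus with >= 2 species in the matrix, plus the
    across-genera summary (mean of the profile means and its SD).

    Singleton genera are skipped with a log entry; undefined pairs are
    dropped with a warning.
    """
    profiles: list[GenusProfile] = []
    by_genus: dict[str, list[str]] = {}
    for label in D.labels:
        by_genus.setdefault(table.genus_of(label), []).append(label)
    for genus in sorted(by_genus):
        members = by_genus[genus]
        if len(members) < 2:
            logger.info("genus %s has a single sequenced species; skipped", genus)
            continue
        dists = []
        n_dropped = 0
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                d = D.get(members[i], members[j])
                if math.isnan(d):
                    n_dropped += 1
                else:
                    dists.append(d)
        if n_dropped:
            logger.warning(
                "genus %s: %d undefined within-genus pair(s) dropped",
                genus,
                n_dropped,
            )
        if not dists:
            logger.warning("genus %s: no defined within-genus pairs; skipped", genus)
            continue
        arr = np.asarray(dists, dtype=float)
        profiles.append(
            GenusProfile(
                genus=genus,
                n_species=len(members),
                mean_within=float(arr.mean()),
                sd_within=float(arr.std(ddof=ddof)) if arr.size > 1 else None,
            )
        )
    means = np.asarray([p.mean_within for p in profiles], dtype=float)
    summary = {
        "n_genera": len(profiles),
        "grand_mean": float(means.mean()) if means.size else None,
        "grand_sd": float(means.std(ddof=1)) if means.size > 1 else None,
    }
    return profiles, summary


# ---------------------------------------------------------------------------
# gap scan

def gap_scan(cmps_or_means: Sequence) -> list[tuple[int, float, float]]:
    """Rank comparison means descending and report the drop to the next one.

    Accepts filled :class:`SisterComparison` objects or plain mean values.
    Returns ``[(rank, mean, gap_to_next), ...]`` with ``rank`` starting at 1;
    a single comparison yields an empty list.  A disproportionate top gap
    flags an outlier divergence (a candidate for elevation above genus).
    """
    means = [
        c.mean if isinstance(c, SisterComparison) else float(c)
        for c in cmps_or_means
    ]
    means = sorted((m for m in means if m is not None), reverse=True)
    return [
        (i + 1, means[i], means[i] - means[i + 1]) for i in range(len(means) - 1)
    ]


# ---------------------------------------------------------------------------
# the five-step protocol

class _WarningCollector(logging.Handler):
    """Captures package warnings during a run so the report can embed them."""

    def __init__(self):
        super().__init__(level=logging.WARNING)
        self.messages: list[str] = []

    def emit(self, record):
        self.messages.append(record.getMessage())


@dataclass
class ProtocolReport:
    """Full output of the genus-rank protocol (JSON-serializable via
    :meth:`to_dict`)."""

    monophyly: dict
    comparisons: list
    distribution: SigmaDistribution
    verdicts: dict
    profiles: list
    within_summary: dict
    gaps: list
    n_undefined_pairs: int
    warnings: list

    def to_dict(self) -> dict:
        return {
            "monophyly": self.monophyly,
            "comparisons": [
                {
                    "node_id": c.node_id,
                    "focal_genus": c.focal_genus,
                    "sister_genera": sorted(c.sister_genera),
                    "n_pairs": c.n_pairs,
                    "mean": c.mean,
                    "sd": c.sd,
                }
                for c in self.comparisons
            ],
            "aggregate": {
                "n": self.distribution.n,
                "mu": self.distribution.mu,
                "sigma": self.distribution.sigma,
                "shapiro_W": self.distribution.shapiro_W,
                "shapiro_p": self.distribution.shapiro_p,
                "band_edges": self.distribution.band_edges,
            },
            "verdicts": {
                label: {
                    "value": v.focal_value,
                    "band": v.band.value,
                    "supports_genus_rank": v.supports_genus_rank,
                }
                for label, v in self.verdicts.items()
            },
            "within_genus": {
                "profiles": [
                    {
                        "genus": p.genus,
                        "n_species": p.n_species,
                        "mean_within": p.mean_within,
                        "sd_within": p.sd_within,
                    }
                    for p in self.profiles
                ],
                "summary": self.within_summary,
            },
            "gap_scan": [
                {"rank": r, "mean": m, "gap_to_next": g} for r, m, g in self.gaps
            ],
            "n_undefined_pairs": self.n_undefined_pairs,
            "warnings": self.warnings,
        }


def run_protocol(seqs, table, gtree, config=None) -> ProtocolReport:
    """Execute the five-step genus-rank procedure on validated inputs.

    1. audit monophyly of every genus in the tree;
    2. enumerate sister comparisons from the phylogeny (after exclusions
       and sensu-lato aliases);
    3. compute the K2P matrix and per-comparison statistics;
    4. aggregate the comparison means into the reference distribution with
       a Shapiro-Wilk normality check;
    5. classify every comparison's focal divergence into a band.

    The report also carries within-genus profiles, the ranked gap scan, and
    every warning raised along the way.  A non-monophyletic genus halts with
    a remediation message unless ``config.allow_nonmonophyletic`` is set.
    """
    from .alignments import select_representatives
    from .config import RunConfig
    from .k2p import distance_matrix
    from .sisters import GenusTree, enumerate_comparisons

    config = config or RunConfig()
    collector = _WarningCollector()
    logger.addHandler(collector)
    try:
        table = table.with_aliases(config.aliases)
        gtree = GenusTree(gtree.tree, table)  # rebind tips to aliased genera
        # step 1: monophyly audit over every genus present in the tree
        monophyly = {g: gtree.is_monophyletic(g) for g in gtree.genera_present}
        bad = [
            g
            for g, ok in monophyly.items()
            if not ok and g not in config.exclusions
        ]
        if bad and not config.allow_nonmonophyletic:
            raise MonophylyError(
                f"non-monophyletic genera: {bad}. Fix the taxonomy (split or "
                "merge), exclude them, or set allow_nonmonophyletic to audit "
                "and continue."
            )
        # step 2: comparison enumeration
        cmps = enumerate_comparisons(
            gtree,
            exclusions=set(config.exclusions) | set(bad),
            require_monophyly=not config.allow_nonmonophyletic,
        )
        if len(cmps) < 2:
            raise InsufficientDataError(
                f"only {len(cmps)} sister comparison(s) available; the "
                "reference distribution needs at least 2 (is there more than "
                "one genus?)"
            )
        # step 3: distances and per-comparison statistics
        reps = select_representatives(seqs, table)
        D = distance_matrix(reps, deletion=config.deletion_mode)
        cmps = [comparison_stats(c, D, ddof=config.ddof) for c in cmps]
        # step 4: aggregate distribution + normality check
        dist = aggregate_distribution(cmps)
        # step 5: classification of every comparison's focal divergence
        verdicts = {c.label: classify(c.mean, dist) for c in cmps}
        profiles, within_summary = within_genus_profiles(
            D, table, ddof=config.ddof
        )
        gaps = gap_scan(cmps)
        return ProtocolReport(
            monophyly=monophyly,
            comparisons=cmps,
            distribution=dist,
            verdicts=verdicts,
            profiles=profiles,
            within_summary=within_summary,
            gaps=gaps,
            n_undefined_pairs=D.n_undefined_pairs,
            warnings=list(collector.messages),
        )
    finally:
        logger.removeHandler(collector)
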