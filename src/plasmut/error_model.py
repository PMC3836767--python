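"""Per-substitution-type null models of sequencing read error.

Amplicon deep sequencing of cell-free DNA introduces position- and
pattern-specific read errors (PCR plus sequencing).  To call a rare mutant
allele, the observed event count at a locus — expressed as events per 100,000
reads — is compared against a null distribution of the read-error rate (RER)
fitted from a panel of normal samples.  Three null families are used, chosen
per substitution type from the panel moments:

1. mean < 1 per 100,000 reads      -> Poisson with a conservative floor
                                      intensity of lambda = 1;
2. mean >= 1, variance/mean <= 1.2 -> Poisson, lambda = ceil(mean);
3. mean >= 1, variance/mean >  1.2 -> negative binomial (gamma-mixed Poisson,
                                      the standard overdispersed count model),
                                      parameters by the method of moments with
                                      r rounded up to an integer.

A base change is judged a mutation when its events per 100,000 reads equal or
exceed the threshold T = min{k >= 0 : P(X > k) <= alpha}, with a per-test
significance of alpha = 2e-5 by default (no multiplicity correction).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ALPHA_DEFAULT",
    "RATIO_CUTOFF_DEFAULT",
    "R_CAP",
    "POISSON_FLOOR",
    "POISSON",
    "NEGATIVE_BINOMIAL",
    "InsufficientPanelError",
    "DispersionError",
    "SubstitutionType",
    "MomentSummary",
    "ErrorModel",
    "ErrorPanelMatrix",
    "normalize_to_per100k",
    "compute_moments",
    "select_model",
    "fit_poisson",
    "fit_negative_binomial",
    "fit_type",
    "upper_tail_prob",
    "compute_threshold",
    "detection_limit",
]

#: per-test significance level for each single detection
ALPHA_DEFAULT = 2e-5
#: variance/mean ratio separating Poisson from negative binomial
RATIO_CUTOFF_DEFAULT = 1.2
#: dispersion cap; above this the NB is numerically a Poisson
R_CAP = 10**6

POISSON_FLOOR = "poisson_floor"
POISSON = "poisson"
NEGATIVE_BINOMIAL = "negative_binomial"

_BASES = frozenset("ACGT")
#: pseudo alt-base marking the pooled insertion/deletion channel of a position
INDEL_ALT = "*"


class InsufficientPanelError(ValueError):
    """Fewer normal-panel samples than moment estimation requires."""


class DispersionError(ValueError):
    """Negative-binomial fit requested although variance <= mean."""


@dataclass(frozen=True, order=True)
class SubstitutionType:
    """One (amplicon, position, ref base -> alt base) conversion pattern.

    ``position`` is the 1-based cDNA coordinate (position 1 = the A of the
    ATG start codon).  ``alt_base`` may be ``"*"`` for the pooled
    insertion/deletion pseudo-type of a position (insertions and deletions
    are not distinguished, as aligners frequently confuse them).
    """

    amplicon_id: str
    position: int
    ref_base: str
    alt_base: str

    def __post_init__(self) -> None:
        if self.ref_base not in _BASES:
            raise ValueError(f"ref_base must be one of ACGT, got {self.ref_base!r}")
        if self.alt_base != INDEL_ALT and self.alt_base not in _BASES:
            raise ValueError(f"alt_base must be one of ACGT or '*', got {self.alt_base!r}")
        if self.alt_base == self.ref_base:
            raise ValueError("alt_base must differ from ref_base")
        if self.position < 1:
            raise ValueError("position is 1-based and must be >= 1")

    @property
    def is_indel(self) -> bool:
        return self.alt_base == INDEL_ALT

    @property
    def label(self) -> str:
        return f"{self.amplicon_id}:{self.position}:{self.ref_base}>{self.alt_base}"

    def __str__(self) -> str:  # pragma: no cover - trivial
        return self.label

    @classmethod
    def from_label(cls, label: str) -> "SubstitutionType":
        amp, pos, change = label.rsplit(":", 2)
        ref, alt = change.split(">")
        return cls(amp, int(pos), ref, alt)


@dataclass(frozen=True)
class MomentSummary:
    """Mean and variance of events per 100,000 reads across the panel."""

    mean: float
    variance: float

    def __post_init__(self) -> None:
        if self.mean < 0 or self.variance < 0:
            raise ValueError("moments must be non-negative")

    @property
    def ratio(self) -> float | None:
        """variance/mean; None (undefined) when the mean is 0."""
        if self.mean == 0:
            return None
        return self.variance / self.mean


def normalize_to_per100k(count: float, depth: int) -> float:
    """Convert an event count at ``depth`` reads to events per 100,000 reads."""
    if depth <= 0:
        raise ValueError(f"depth must be positive, got {depth}")
    if count < 0:
        raise ValueError(f"count must be non-negative, got {count}")
    return count * 100_000.0 / depth


def compute_moments(rates: Sequence[float] | np.ndarray, ddof: int = 0) -> MomentSummary:
    """Method-of-moments summary of per-100k rates across panel samples.

    ``ddof=0`` (population variance, the method-of-moments convention) is the
    default; ``ddof=1`` is available for the sample-variance convention.
    """
    arr = np.asarray(rates, dtype=float)
    if arr.ndim != 1:
        raise ValueError("rates must be one-dimensional")
    if arr.size < 2:
        raise InsufficientPanelError(
            f"moment estimation needs at least 2 panel samples, got {arr.size}"
        )
    if np.any(arr < 0):
        raise ValueError("rates must be non-negative")
    return MomentSummary(mean=float(arr.mean()), variance=float(arr.var(ddof=ddof)))


def select_model(
    ms: MomentSummary,
    ratio_cutoff: float = RATIO_CUTOFF_DEFAULT,
    floor_mean: float = 1.0,
) -> str:
    """Pick the null family from the panel moments.

    A variance/mean ratio exactly at the cutoff is assigned to the Poisson
    family (ties favour the simpler model).
    """
    if ms.mean < floor_mean:
        return POISSON_FLOOR
    ratio = ms.ratio
    if ratio is None or ratio <= ratio_cutoff:
        return POISSON
    return NEGATIVE_BINOMIAL


def _ceil(x: float) -> int:
    # guard against float noise pushing an exact integer over the next step
    return int(math.ceil(round(x, 9)))


@dataclass(frozen=True)
class ErrorModel:
    """A fitted null error distribution with its anomaly threshold.

    ``threshold`` is the minimum events per 100,000 reads judged a mutation:
    T = min{k : P(X > k) <= alpha}.  The calling rule is "events >= T", so
    the realized per-test size is P(X >= T) = sf(T - 1), which may slightly
    exceed ``alpha``; both numbers are carried so users can see the gap.
    """

    kind: str
    alpha: float
    threshold: int
    mean: float
    variance: float
    lam: int | None = None
    r: int | None = None
    p: float | None = None

    def __post_init__(self) -> None:
        if self.kind in (POISSON, POISSON_FLOOR):
            if self.lam is None or self.lam < 1:
                raise ValueError("Poisson models need an integer lambda >= 1")
            if self.kind == POISSON_FLOOR and self.lam != 1:
                raise ValueError("the Poisson floor model has lambda = 1")
        elif self.kind == NEGATIVE_BINOMIAL:
            if self.r is None or self.r < 1:
                raise ValueError("NB models need an integer r >= 1")
            if self.p is None or not (0.0 < self.p < 1.0):
                raise ValueError("NB models need p in (0, 1)")
        else:
            raise ValueError(f"unknown model kind {self.kind!r}")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if self.threshold < 0:
            raise ValueError("threshold must be non-negative")

    @cached_property
    def distribution(self):
        """The frozen scipy distribution of the event count X."""
        if self.kind == NEGATIVE_BINOMIAL:
            return stats.nbinom(self.r, self.p)
        return stats.poisson(self.lam)

    def sf(self, k: int) -> float:
        """P(X > k)."""
        return float(self.distribution.sf(k))

    def tail_geq(self, k: int) -> float:
        """P(X >= k)."""
        return float(self.distribution.sf(k - 1))

    @property
    def realized_size(self) -> float:
        """P(X >= threshold), the per-test size actually realized by calling."""
        return self.tail_geq(self.threshold)

    @property
    def model_mean(self) -> float:
        """Mean of the fitted distribution (after integer rounding)."""
        if self.kind == NEGATIVE_BINOMIAL:
            return self.r * (1.0 - self.p) / self.p
        return float(self.lam)

    def to_dict(self) -> dict:
        d = {
            "kind": self.kind,
            "alpha": self.alpha,
            "threshold": self.threshold,
            "mean": self.mean,
            "variance": self.variance,
            "realized_size": self.realized_size,
        }
        if self.kind == NEGATIVE_BINOMIAL:
            d.update(r=self.r, p=self.p)
        else:
            d.update({"lambda": self.lam})
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "ErrorModel":
        return cls(
            kind=d["kind"],
            alpha=d["alpha"],
            threshold=d["threshold"],
            mean=d["mean"],
            variance=d["variance"],
            lam=d.get("lambda"),
            r=d.get("r"),
            p=d.get("p"),
        )


def _threshold_from_sf(sf, alpha: float) -> int:
    k = 0
    while sf(k) > alpha:
        k += 1
    return k


def compute_threshold(model: ErrorModel, alpha: float | None = None) -> int:
    """Minimum events per 100,000 reads judged a mutation.

    T = min{k >= 0 : P(X > k) <= alpha}, found by exact survival-function
    evaluation.  For the lambda = 1 floor at alpha = 2e-5 this yields T = 7.
    """
    a = model.alpha if alpha is None else alpha
    if not (0.0 < a < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    return _threshold_from_sf(model.sf, a)


def fit_poisson(
    ms: MomentSummary, floor: bool, alpha: float = ALPHA_DEFAULT
) -> ErrorModel:
    """Fit a Poisson null: lambda = 1 (floor) or ceil(mean), minimum 1."""
    lam = 1 if floor else max(1, _ceil(ms.mean))
    kind = POISSON_FLOOR if floor else POISSON
    model = ErrorModel(
        kind=kind, alpha=alpha, threshold=0, mean=ms.mean, variance=ms.variance, lam=lam
    )
    return ErrorModel(
        kind=kind,
        alpha=alpha,
        threshold=compute_threshold(model),
        mean=ms.mean,
        variance=ms.variance,
        lam=lam,
    )


def fit_negative_binomial(ms: MomentSummary, alpha: float = ALPHA_DEFAULT) -> ErrorModel:
    """Fit an NB null by the method of moments with integer round-up of r.

    r = ceil(mean^2 / (variance - mean)); p is then re-solved as
    p = r / (r + mean) so the fitted distribution keeps the empirical mean
    (the better-estimated moment) after rounding.  If the overdispersion is
    so small that r would exceed 1e6, the NB is numerically a Poisson and a
    Poisson fit is returned with a warning.
    """
    if ms.variance <= ms.mean:
        raise DispersionError(
            f"variance ({ms.variance}) must exceed mean ({ms.mean}) for an NB fit; "
            "run select_model first"
        )
    r = _ceil(ms.mean**2 / (ms.variance - ms.mean))
    if r > R_CAP:
        warnings.warn(
            f"dispersion parameter r={r} exceeds {R_CAP}; falling back to Poisson",
            RuntimeWarning,
            stacklevel=2,
        )
        return fit_poisson(ms, floor=False, alpha=alpha)
    r = max(1, r)
    p = r / (r + ms.mean)
    model = ErrorModel(
        kind=NEGATIVE_BINOMIAL,
        alpha=alpha,
        threshold=0,
        mean=ms.mean,
        variance=ms.variance,
        r=r,
        p=p,
    )
    return ErrorModel(
        kind=NEGATIVE_BINOMIAL,
        alpha=alpha,
        threshold=compute_threshold(model),
        mean=ms.mean,
        variance=ms.variance,
        r=r,
        p=p,
    )


def fit_type(
    rates: Sequence[float] | np.ndarray,
    alpha: float = ALPHA_DEFAULT,
    ratio_cutoff: float = RATIO_CUTOFF_DEFAULT,
    ddof: int = 0,
) -> ErrorModel:
    """Moments -> family selection -> fit -> threshold, for one type."""
    ms = compute_moments(rates, ddof=ddof)
    kind = select_model(ms, ratio_cutoff=ratio_cutoff)
    if kind == POISSON_FLOOR:
        return fit_poisson(ms, floor=True, alpha=alpha)
    if kind == POISSON:
        return fit_poisson(ms, floor=False, alpha=alpha)
    return fit_negative_binomial(ms, alpha=alpha)


def upper_tail_prob(model: ErrorModel, k: int) -> float:
    """Exact P(X > k) for a fitted model."""
    if k < 0:
        raise ValueError("k must be non-negative")
    return model.sf(k)


def detection_limit(
    model: ErrorModel,
    depth: int,
    alpha: float | None = None,
    mean_adjusted: bool = False,
) -> float:
    """Smallest callable mutant fraction (percent) at a given read depth.

    The fitted intensity is rescaled (real-valued) to the depth: a Poisson
    model uses lambda_d = lambda * depth / 100,000; an NB model keeps its
    dispersion r and rescales the mean the same way.  The limit is
    100 * T_d / depth, where T_d is the threshold at the rescaled depth —
    the smallest fraction whose event count alone reaches the threshold.
    ``mean_adjusted=True`` instead reports 100 * (T_d - mean_d) / depth, the
    fraction needed on top of the expected background error.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    a = model.alpha if alpha is None else alpha
    scale = depth / 100_000.0
    if model.kind == NEGATIVE_BINOMIAL:
        mean_d = model.model_mean * scale
        p_d = model.r / (model.r + mean_d)
        dist = stats.nbinom(model.r, p_d)
    else:
        mean_d = model.lam * scale
        dist = stats.poisson(mean_d)
    t_d = _threshold_from_sf(lambda k: float(dist.sf(k)), a)
    numer = t_d - mean_d if mean_adjusted else t_d
    return 100.0 * numer / depth


@dataclass
class ErrorPanelMatrix:
    """Normal-panel event counts for every substitution type.

    ``counts`` and ``depths`` are (type label x sample) DataFrames of raw
    event counts and total scored reads; ``rates`` (events per 100,000 reads,
    count * 100,000 / depth cell-wise) is derived so the defining identity
    always holds.  ``excluded`` lists type labels withheld from model fitting
    (known germline SNPs; by default the G>A conversion at cDNA position
    2361, a frequent SNP).
    """

    counts: pd.DataFrame
    depths: pd.DataFrame
    excluded: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.depths.index) or not self.counts.columns.equals(
            self.depths.columns
        ):
            raise ValueError("counts and depths must share index and columns")
        if (self.depths.to_numpy() <= 0).any():
            raise ValueError("depths must be positive")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        unknown = set(self.excluded) - set(self.counts.index)
        if unknown:
            raise ValueError(f"excluded types absent from the panel: {sorted(unknown)}")

    @cached_property
    def rates(self) -> pd.DataFrame:
        return self.counts * 100_000.0 / self.depths

    @property
    def types(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def fitting_rates(self) -> pd.DataFrame:
        """Rates with SNP-excluded types dropped, as used for model fitting."""
        return self.rates.drop(index=self.excluded)

    @classmethod
    def from_long(
        cls, table: pd.DataFrame, excluded: Iterable[str] = ()
    ) -> "ErrorPanelMatrix":
        """Build from a long table with columns amplicon, position, ref, alt,
        sample, count, depth (the panel TSV schema)."""
        required = {"amplicon", "position", "ref", "alt", "sample", "count", "depth"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"panel table is missing columns: {sorted(missing)}")
        t = table.copy()
        t["label"] = (
            t["amplicon"].astype(str)
            + ":"
            + t["position"].astype(str)
            + ":"
            + t["ref"].astype(str)
            + ">"
            + t["alt"].astype(str)
        )
        counts = t.pivot(index="label", columns="sample", values="count")
        depths = t.pivot(index="label", columns="sample", values="depth")
        if counts.isna().any().any() or depths.isna().any().any():
            raise ValueError("panel table must cover every (type, sample) cell")
        return cls(counts=counts, depths=depths, excluded=list(excluded))

    def to_long(self) -> pd.DataFrame:
        """Inverse of :meth:`from_long` (label split back into columns)."""
        rows = []
        for label in self.counts.index:
            amp, pos, change = label.rsplit(":", 2)
            ref, alt = change.split(">")
            for sample in self.counts.columns:
                rows.append(
                    {
                        "amplicon": amp,
                        "position": int(pos),
                        "ref": ref,
                        "alt": alt,
                        "sample": sample,
                        "count": int(self.counts.at[label, sample]),
                        "depth": int(self.depths.at[label, sample]),
                    }
                )
        return pd.DataFrame(rows)
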