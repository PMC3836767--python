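"""Mutation calling against fitted error models.

A base change is judged a mutation when its observed events per 100,000
reads equal or exceed the type's threshold.  The comparison uses the
real-valued normalized count (no rounding), which is monotone in depth and
reproduces the integer behaviour exactly at the 100,000-read reference
depth.  Alongside the binary call the realized upper-tail probability
P(X >= observed) is reported, so the per-test size actually spent at the
threshold is visible.

Mutant fractions are raw count / depth for substitutions, and chosen-template
reads / all exon-19 reads for the deletion.  Estimates below the ~0.3%
quantitation limit (set by the ~5,000-molecule assay input bottleneck) are
flagged: the call may be real, but its magnitude is not reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .amplicon import (
    DELETION_LABEL,
    SNP_EXCLUDED_LABELS,
    TARGET_SUBSTITUTIONS,
    PileupCounts,
    deletion_fraction,
)
from .error_model import ErrorModel, SubstitutionType, normalize_to_per100k

__all__ = [
    "QUANTITATION_LIMIT_PERCENT",
    "MutationCall",
    "SampleReport",
    "TemporalSeries",
    "call_substitution",
    "call_exon19_deletion",
    "scan_region",
    "quantify",
    "call_sample",
    "temporal_report",
]

#: smallest mutant fraction (percent) quantified reproducibly
QUANTITATION_LIMIT_PERCENT = 0.3


@dataclass(frozen=True)
class MutationCall:
    """Per-locus anomaly decision."""

    locus: str
    kind: str  # "substitution" | "deletion"
    count: int
    depth: int
    events_per_100k: float
    threshold: int
    tail_prob: float
    called: bool
    fraction_percent: float
    below_quantitation: bool
    sub_type: SubstitutionType | None = None
    chosen_template: str | None = None

    @property
    def events_per_10k(self) -> float:
        return self.events_per_100k / 10.0

    def to_dict(self) -> dict:
        d = {
            "locus": self.locus,
            "kind": self.kind,
            "count": self.count,
            "depth": self.depth,
            "events_per_100k": self.events_per_100k,
            "threshold": self.threshold,
            "tail_prob": self.tail_prob,
            "called": self.called,
            "fraction_percent": self.fraction_percent,
            "below_quantitation": self.below_quantitation,
        }
        if self.sub_type is not None:
            d["type"] = self.sub_type.label
        if self.chosen_template is not None:
            d["chosen_template"] = self.chosen_template
        return d


def _decide(
    locus: str,
    kind: str,
    count: int,
    depth: int,
    model: ErrorModel,
    fraction_percent: float,
    sub_type: SubstitutionType | None = None,
    chosen_template: str | None = None,
) -> MutationCall:
    events = normalize_to_per100k(count, depth)
    called = events >= model.threshold
    tail = model.tail_geq(int(math.ceil(round(events, 9))))
    return MutationCall(
        locus=locus,
        kind=kind,
        count=count,
        depth=depth,
        events_per_100k=events,
        threshold=model.threshold,
        tail_prob=tail,
        called=called,
        fraction_percent=fraction_percent,
        below_quantitation=called and fraction_percent < QUANTITATION_LIMIT_PERCENT,
        sub_type=sub_type,
        chosen_template=chosen_template,
    )


def call_substitution(
    pileup: PileupCounts,
    model: ErrorModel,
    sub_type: SubstitutionType,
    locus: str | None = None,
) -> MutationCall:
    """Call one substitution locus from a pileup and its fitted null model."""
    if model is None:
        raise ValueError(f"no fitted model for {sub_type.label}")
    depth = pileup.depth_at(sub_type.position)
    if depth <= 0:
        raise ZeroDivisionError(f"no coverage at {sub_type.label}")
    count = pileup.count_at(sub_type.position, sub_type.alt_base)
    return _decide(
        locus=locus or sub_type.label,
        kind="substitution",
        count=count,
        depth=depth,
        model=model,
        fraction_percent=100.0 * count / depth,
        sub_type=sub_type,
    )


def call_exon19_deletion(
    template_counts: Mapping[str, int],
    exon19_total: int,
    model: ErrorModel,
    numerator: str = "chosen",
) -> MutationCall:
    """Call the exon-19 deletion from template-screen read counts.

    The event count is that of the template with the most assigned reads
    (ties to the smallest template id); the fraction divides deletion-type
    reads by all exon-19-aligned reads.
    """
    if exon19_total <= 0:
        raise ZeroDivisionError("no exon-19 aligned reads")
    if template_counts:
        chosen = min(template_counts, key=lambda tid: (-template_counts[tid], tid))
        count = template_counts[chosen]
        if count == 0:
            chosen = None
    else:
        chosen, count = None, 0
    fraction = deletion_fraction(template_counts, exon19_total, numerator=numerator)
    return _decide(
        locus="exon19del",
        kind="deletion",
        count=count,
        depth=exon19_total,
        model=model,
        fraction_percent=100.0 * fraction,
        chosen_template=chosen,
    )


def quantify(call: MutationCall, limit_percent: float = QUANTITATION_LIMIT_PERCENT) -> MutationCall:
    """Re-apply the quantitation flag, optionally at a non-default limit."""
    return replace(
        call,
        below_quantitation=call.called and call.fraction_percent < limit_percent,
    )


def scan_region(
    pileups: Mapping[str, PileupCounts],
    models: Mapping[str, ErrorModel],
    exclude: Iterable[str] | None = None,
    include_not_called: bool = False,
) -> list[MutationCall]:
    """Evaluate every modeled substitution type across the target region.

    The named target loci and excluded SNPs are skipped (503 scanned types
    with the default 507-type region), as are indel pseudo-types and the
    deletion channel.  By default only called types are returned; set
    ``include_not_called`` to get one call per scanned type.
    """
    if exclude is None:
        exclude = {st.label for st in TARGET_SUBSTITUTIONS.values()}
        exclude |= set(SNP_EXCLUDED_LABELS)
    else:
        exclude = set(exclude)
    out = []
    for label, model in models.items():
        if label in exclude or label == DELETION_LABEL:
            continue
        try:
            st = SubstitutionType.from_label(label)
        except (ValueError, KeyError):
            continue
        if st.is_indel:
            continue
        pile = pileups.get(st.amplicon_id)
        if pile is None:
            continue
        call = call_substitution(pile, model, st)
        if call.called or include_not_called:
            out.append(call)
    return out


@dataclass
class SampleReport:
    """All calls for one sample: target loci plus whole-region scan."""

    sample_id: str
    calls: dict[str, MutationCall]
    scan_calls: list[MutationCall] = field(default_factory=list)
    depths: dict[str, int] = field(default_factory=dict)
    model_version: str = ""

    def __post_init__(self) -> None:
        for name, call in self.calls.items():
            if call.locus != name:
                raise ValueError(f"call labelled {call.locus!r} stored under {name!r}")

    @property
    def called_mutations(self) -> dict[str, MutationCall]:
        return {k: c for k, c in self.calls.items() if c.called}

    def to_dict(self) -> dict:
        return {
            "sample": self.sample_id,
            "model_version": self.model_version,
            "depths": self.depths,
            "calls": {k: c.to_dict() for k, c in self.calls.items()},
            "scan": [c.to_dict() for c in self.scan_calls],
        }


def call_sample(
    sample_id: str,
    pileups: Mapping[str, PileupCounts],
    template_counts: Mapping[str, int],
    exon19_total: int,
    models: Mapping[str, ErrorModel],
    scan: bool = True,
    numerator: str = "chosen",
    model_version: str = "",
) -> SampleReport:
    """Assemble the per-sample report: four target loci and optional scan."""
    calls: dict[str, MutationCall] = {}
    del_model = models.get(DELETION_LABEL)
    if del_model is None:
        raise KeyError(f"missing model for the deletion channel {DELETION_LABEL!r}")
    calls["exon19del"] = replace(
        call_exon19_deletion(template_counts, exon19_total, del_model, numerator=numerator),
        locus="exon19del",
    )
    for name, st in TARGET_SUBSTITUTIONS.items():
        model = models.get(st.label)
        if model is None:
            raise KeyError(f"missing model for target locus {name} ({st.label})")
        calls[name] = call_substitution(pileups[st.amplicon_id], model, st, locus=name)
    scan_calls = scan_region(pileups, models) if scan else []
    depths = {amp: int(np.max(p.depth)) if len(p.depth) else 0 for amp, p in pileups.items()}
    return SampleReport(
        sample_id=sample_id,
        calls=calls,
        scan_calls=scan_calls,
        depths=depths,
        model_version=model_version,
    )


@dataclass
class TemporalSeries:
    """Called mutations per timepoint, scaled to events per 10,000 reads."""

    patient_id: str
    timepoints: list[str]
    entries: list[dict[str, float]]

    def __post_init__(self) -> None:
        if len(self.timepoints) != len(self.entries):
            raise ValueError("one entry per timepoint required")

    def to_dict(self) -> dict:
        return {
            "patient": self.patient_id,
            "timepoints": self.timepoints,
            "mutations_per_10k": self.entries,
        }

    def plot(self, ax=None):
        """Plot called mutations per 10,000 reads over the sampling order
        (log scale; only the order of timepoints is meaningful)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        mutations = sorted({name for entry in self.entries for name in entry})
        x = np.arange(len(self.timepoints))
        for name in mutations:
            y = [entry.get(name, np.nan) for entry in self.entries]
            ax.plot(x, y, marker="o", label=name)
        ax.set_xticks(x, self.timepoints)
        ax.set_yscale("log")
        ax.set_xlabel("sampling order")
        ax.set_ylabel("mutations per 10,000 reads")
        ax.set_title(f"patient {self.patient_id}")
        if mutations:
            ax.legend()
        return ax


def temporal_report(
    reports: Sequence[SampleReport], patient_id: str
) -> TemporalSeries:
    """Order-preserving series of called mutations, per 10,000 reads.

    Only mutations exceeding their thresholds are emitted; timepoints with
    no calls keep an empty entry so the sampling order stays visible.
    """
    if len(reports) < 1:
        raise ValueError("at least one timepoint is required")
    timepoints, entries = [], []
    for report in reports:
        timepoints.append(report.sample_id)
        entries.append(
            {name: c.events_per_10k for name, c in report.called_mutations.items()}
        )
    return TemporalSeries(patient_id=patient_id, timepoints=timepoints, entries=entries)
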