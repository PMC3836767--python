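"""Synthetic normal panels, assays, and reads with the error structure the
caller assumes.

The generator emulates the statistical landscape of amplicon deep sequencing
on a semiconductor sequencer:

* per-position substitution error with one dominant alternate base per
  position (the dominant pattern carries 80% of the position's error mass by
  default);
* gamma-fluctuating error intensities (so event counts are negative-binomial
  overdispersed for most types with mean >= 1 per 100,000 reads);
* per-sample read depths drawn uniformly from 44,400-373,000 (mean ~162,000);
* an assay template bottleneck of ~5,000 input molecules, which caps the
  reproducibility of fraction estimates near 0.3%;
* position-specific insertion/deletion error far exceeding substitution
  error, which is why exon-19 deletions are screened by template matching
  rather than read off the pileup.

Intensities are parameterised per 100,000 reads at the reference depth; a
process with ``ratio`` rho > 1 mixes the Poisson intensity with a gamma of
shape mean/(rho-1) and scale (rho-1), giving variance/mean = rho at the
reference depth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .amplicon import (
    DELETION_LABEL,
    AmpliconReference,
    DeletionTemplate,
    IndexedRead,
    PileupCounts,
    TARGET_SUBSTITUTIONS,
    default_references,
    deletion_templates,
    reference_map,
)
from .error_model import ErrorPanelMatrix, SubstitutionType

__all__ = [
    "ErrorProcess",
    "PanelSpec",
    "AssaySpec",
    "AssayResult",
    "default_panel_spec",
    "simulate_normal_panel",
    "simulate_assay",
    "simulate_dilution_series",
    "simulate_duplicate_assays",
    "simulate_reads",
]

#: per-sample read-depth range observed across normal-panel assays
DEPTH_RANGE_DEFAULT = (44_400, 373_000)
#: input molecules available to one plasma assay
TEMPLATE_MOLECULES_DEFAULT = 5_000


@dataclass(frozen=True)
class ErrorProcess:
    """Error-generating process for one substitution type.

    ``mean`` is events per 100,000 reads at the reference depth; ``ratio``
    is the target variance/mean of the count at that depth (1 = pure
    Poisson, > 1 = gamma-mixed Poisson).
    """

    mean: float
    ratio: float = 1.0

    def __post_init__(self) -> None:
        if self.mean < 0:
            raise ValueError("mean must be non-negative")
        if self.ratio < 1.0:
            raise ValueError("ratio must be >= 1 (<= Poisson is not modeled)")

    def intensities(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """Per-sample intensity draws (per 100,000 reads)."""
        if self.mean == 0:
            return np.zeros(n)
        if self.ratio <= 1.0:
            return np.full(n, self.mean)
        scale = self.ratio - 1.0
        shape = self.mean / scale
        return rng.gamma(shape, scale, size=n)


@dataclass(frozen=True)
class PanelSpec:
    """Generating processes for a simulated panel of normal samples."""

    processes: Mapping[str, ErrorProcess]
    n_samples: int = 48
    depth_range: tuple[int, int] = DEPTH_RANGE_DEFAULT
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("a panel needs at least 2 samples")
        lo, hi = self.depth_range
        if not (0 < lo <= hi):
            raise ValueError("depth_range must be positive and ordered")


def default_panel_spec(
    seed: int | None = None,
    n_samples: int = 48,
    dominant_share: float = 0.8,
    include_indels: bool = True,
    references: Sequence[AmpliconReference] | None = None,
) -> PanelSpec:
    """Panel spec emulating the observed EGFR-region error landscape.

    Per position, the total substitution error mass (per 100,000 reads) is
    drawn log-uniformly from [1, 120] and split 80/10/10 across the three
    alternate bases with a random dominant pattern; with this choice ~1/3 of
    types fall below mean 1 (the Poisson-floor category) and ~82% below 10
    per 100k (RER < 0.01%).  Each type is pure Poisson with probability 0.05,
    otherwise gamma-mixed with variance/mean drawn uniformly from [1.5, 4].
    Indel pseudo-types draw their mass log-uniformly from [0.5, 300] (about
    half the positions exceed RER 0.01%) with stronger overdispersion.

    The four target loci are pinned to the error behaviour of the assay:
    near-zero error for the exon-19 deletion channel (template screening
    removes deletion read errors) and for L858R; Poisson mean 2.6 for L861Q;
    gamma-mixed mean 20, variance/mean 3 for T790M.
    """
    rng = np.random.default_rng(seed)
    refs = default_references() if references is None else tuple(references)
    processes: dict[str, ErrorProcess] = {}
    for ref in refs:
        for pos in ref.window_positions:
            ref_base = ref.base_at(pos)
            alts = [b for b in "ACGT" if b != ref_base]
            mass = math.exp(rng.uniform(math.log(1.0), math.log(120.0)))
            dominant = alts[rng.integers(len(alts))]
            for alt in alts:
                share = dominant_share if alt == dominant else (1 - dominant_share) / 2
                ratio = 1.0 if rng.random() < 0.05 else float(rng.uniform(1.5, 4.0))
                st = SubstitutionType(ref.amplicon_id, pos, ref_base, alt)
                processes[st.label] = ErrorProcess(mean=mass * share, ratio=ratio)
            if include_indels:
                st = SubstitutionType(ref.amplicon_id, pos, ref_base, "*")
                mass_i = math.exp(rng.uniform(math.log(0.5), math.log(300.0)))
                processes[st.label] = ErrorProcess(
                    mean=mass_i, ratio=float(rng.uniform(2.0, 6.0))
                )
    # target loci: pin to the assay's observed behaviour
    processes[DELETION_LABEL] = ErrorProcess(mean=0.0)
    processes[TARGET_SUBSTITUTIONS["L858R"].label] = ErrorProcess(mean=0.2)
    processes[TARGET_SUBSTITUTIONS["L861Q"].label] = ErrorProcess(mean=2.6)
    processes[TARGET_SUBSTITUTIONS["T790M"].label] = ErrorProcess(mean=20.0, ratio=3.0)
    return PanelSpec(processes=processes, n_samples=n_samples, seed=seed)


def _amplicon_of(label: str) -> str:
    return label.split(":", 1)[0]


def simulate_normal_panel(spec: PanelSpec) -> ErrorPanelMatrix:
    """Draw a normal-panel count matrix under the spec's processes.

    Per sample and amplicon a read depth is drawn; per type and sample an
    intensity (fixed or gamma) is drawn and the count is Poisson with mean
    intensity * depth / 100,000.  Reproducible for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    samples = [f"N{i + 1:02d}" for i in range(spec.n_samples)]
    amplicons = sorted({_amplicon_of(lab) for lab in spec.processes})
    lo, hi = spec.depth_range
    depth_by_amp = {
        amp: rng.integers(lo, hi + 1, size=spec.n_samples) for amp in amplicons
    }
    counts: dict[str, np.ndarray] = {}
    depths: dict[str, np.ndarray] = {}
    for label, proc in spec.processes.items():
        d = depth_by_amp[_amplicon_of(label)]
        lam = proc.intensities(rng, spec.n_samples) * d / 100_000.0
        counts[label] = rng.poisson(lam)
        depths[label] = d
    counts_df = pd.DataFrame(counts, index=samples).T
    depths_df = pd.DataFrame(depths, index=samples).T
    from .amplicon import SNP_EXCLUDED_LABELS

    excluded = [lab for lab in SNP_EXCLUDED_LABELS if lab in counts_df.index]
    return ErrorPanelMatrix(counts=counts_df, depths=depths_df, excluded=excluded)


@dataclass(frozen=True)
class AssaySpec:
    """One simulated plasma assay.

    ``fraction`` is the mutant-allele fraction (0..1); ``mutation`` names a
    target substitution ("L858R", "L861Q", "T790M"), a deletion template id,
    or None for a pure-normal assay.  ``template_molecules`` models the
    pre-PCR input bottleneck (mutant input molecules are binomially sampled
    from it); None disables the bottleneck.
    """

    depth: int = 100_000
    fraction: float = 0.0
    mutation: str | None = None
    template_molecules: int | None = TEMPLATE_MOLECULES_DEFAULT
    processes: Mapping[str, ErrorProcess] | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.fraction <= 1.0):
            raise ValueError("fraction must be in [0, 1]")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.template_molecules is not None and self.template_molecules <= 0:
            raise ValueError("template_molecules must be positive")


@dataclass
class AssayResult:
    """Counts produced by one simulated assay, plus the ground truth."""

    pileups: dict[str, PileupCounts]
    template_counts: dict[str, int]
    exon19_total: int
    depths: dict[str, int]
    truth: dict


def _resolve_mutation(
    mutation: str | None,
) -> tuple[str, SubstitutionType | None, DeletionTemplate | None]:
    if mutation is None:
        return "none", None, None
    if mutation in TARGET_SUBSTITUTIONS:
        return "substitution", TARGET_SUBSTITUTIONS[mutation], None
    templates = {t.template_id: t for t in deletion_templates()}
    if mutation in templates:
        return "deletion", None, templates[mutation]
    raise ValueError(
        f"unknown mutation {mutation!r}; expected one of "
        f"{sorted(TARGET_SUBSTITUTIONS) + sorted(templates)}"
    )


def simulate_assay(
    spec: AssaySpec, rng: np.random.Generator | None = None
) -> AssayResult:
    """Two-stage sampling of one assay's per-position counts.

    Mutant input molecules are drawn Binomial(template_molecules, fraction);
    sequencing reads are then allocated to the mutant allele in proportion to
    the sampled molecules; per-position read errors are added on top under
    the error processes.  Deletion alleles are realized as reads assigned to
    the specified deletion template by the screening step.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    refs = reference_map()
    processes = spec.processes if spec.processes is not None else {}
    kind, sub, template = _resolve_mutation(spec.mutation)

    if spec.template_molecules is not None:
        mutant_templates = int(rng.binomial(spec.template_molecules, spec.fraction))
        template_fraction = mutant_templates / spec.template_molecules
    else:
        mutant_templates = None
        template_fraction = spec.fraction
    n_mut = int(rng.binomial(spec.depth, template_fraction))

    pileups: dict[str, PileupCounts] = {}
    depths: dict[str, int] = {}
    for amp_id, ref in refs.items():
        pile = PileupCounts.empty(ref)
        pile.n_reads = spec.depth
        depths[amp_id] = spec.depth
        for i, pos in enumerate(ref.window_positions):
            ref_base = ref.base_at(pos)
            ref_count = spec.depth
            for alt in "ACGT":
                if alt == ref_base:
                    continue
                st = SubstitutionType(amp_id, pos, ref_base, alt)
                proc = processes.get(st.label)
                err = 0
                if proc is not None and proc.mean > 0:
                    lam = proc.intensities(rng, 1)[0] * spec.depth / 100_000.0
                    err = int(rng.poisson(lam))
                count = err
                if (
                    kind == "substitution"
                    and sub is not None
                    and sub.amplicon_id == amp_id
                    and sub.position == pos
                    and sub.alt_base == alt
                ):
                    count += n_mut
                count = min(count, spec.depth)
                pile.base_counts[alt][i] = count
                ref_count -= count
            pile.base_counts[ref_base][i] = max(ref_count, 0)
        pileups[amp_id] = pile

    template_counts = {t.template_id: 0 for t in deletion_templates()}
    exon19_total = spec.depth
    if kind == "deletion" and template is not None:
        template_counts[template.template_id] = n_mut
        # deletion reads do not contribute reference bases at deleted positions
        pile = pileups["exon19"]
        lo, hi = template.cdna_interval
        for pos in range(lo, hi + 1):
            i = pile._idx(pos)
            ref_base = refs["exon19"].base_at(pos)
            pile.base_counts[ref_base][i] = max(
                pile.base_counts[ref_base][i] - n_mut, 0
            )
            pile.deletions[i] += n_mut

    truth = {
        "fraction": spec.fraction,
        "mutation": spec.mutation,
        "mutant_templates": mutant_templates,
        "mutant_reads": n_mut,
        "depth": spec.depth,
    }
    return AssayResult(
        pileups=pileups,
        template_counts=template_counts,
        exon19_total=exon19_total,
        depths=depths,
        truth=truth,
    )


def _estimated_fraction(result: AssayResult, mutation: str) -> float:
    """Mutant fraction (0..1) read back through the counting path."""
    kind, sub, template = _resolve_mutation(mutation)
    if kind == "substitution":
        pile = result.pileups[sub.amplicon_id]
        depth = pile.depth_at(sub.position)
        return pile.count_at(sub.position, sub.alt_base) / depth
    if kind == "deletion":
        from .amplicon import deletion_fraction

        return deletion_fraction(result.template_counts, result.exon19_total)
    raise ValueError("an assay without a mutation has no mutant fraction")


def simulate_dilution_series(
    fractions: Sequence[float],
    replicates: int = 3,
    spec: AssaySpec | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Dilution series: assays at each mutant fraction, estimated back
    through the counting pipeline.

    ``fractions`` are mutant-allele fractions in percent.  Returns one row
    per (fraction, replicate) with the estimated percent; per-point means
    are the replicate averages (three assays per point by default).
    """
    if len(fractions) == 0:
        raise ValueError("fractions must be non-empty")
    base = spec if spec is not None else AssaySpec(mutation="L858R")
    if base.mutation is None:
        base = replace(base, mutation="L858R")
    rng = np.random.default_rng(seed if seed is not None else base.seed)
    rows = []
    for frac_pct in fractions:
        for rep in range(replicates):
            s = replace(base, fraction=frac_pct / 100.0)
            result = simulate_assay(s, rng=rng)
            est = _estimated_fraction(result, base.mutation)
            rows.append(
                {
                    "true_percent": frac_pct,
                    "replicate": rep + 1,
                    "estimated_percent": 100.0 * est,
                }
            )
    return pd.DataFrame(rows)


def simulate_duplicate_assays(
    n_samples: int = 20,
    fraction_range_percent: tuple[float, float] = (0.3, 50.0),
    spec: AssaySpec | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Paired replicate assays of the same samples (reproducibility design).

    Per sample a true fraction is drawn log-uniformly from the percent range
    and two independent assays (each with its own template bottleneck) are
    run; returns columns true_percent, trial1_percent, trial2_percent.
    """
    base = spec if spec is not None else AssaySpec(mutation="L858R")
    if base.mutation is None:
        base = replace(base, mutation="L858R")
    rng = np.random.default_rng(seed)
    lo, hi = fraction_range_percent
    rows = []
    for i in range(n_samples):
        frac_pct = math.exp(rng.uniform(math.log(lo), math.log(hi)))
        trials = []
        for _ in range(2):
            result = simulate_assay(replace(base, fraction=frac_pct / 100.0), rng=rng)
            trials.append(100.0 * _estimated_fraction(result, base.mutation))
        rows.append(
            {
                "sample": f"S{i + 1:02d}",
                "true_percent": frac_pct,
                "trial1_percent": trials[0],
                "trial2_percent": trials[1],
            }
        )
    return pd.DataFrame(rows)


def simulate_reads(
    n_reads: int,
    index: str = "ACGTA",
    fraction: float = 0.0,
    mutation: str | None = None,
    references: Sequence[AmpliconReference] | None = None,
    per_base_substitution_rate: float = 1e-4,
    per_base_indel_rate: float = 0.0,
    seed: int | None = None,
) -> tuple[list[IndexedRead], dict]:
    """Generate indexed FASTQ-style reads with planted mutations and errors.

    Reads are distributed evenly over the amplicons; a mutant read carries
    the planted substitution or is generated from the deletion-template
    sequence.  With all error rates at zero, every read is an exact
    reference (or template) sequence behind its 5-nt index.  Returns the
    reads and a ground-truth manifest of planted counts.
    """
    rng = np.random.default_rng(seed)
    refs = list(default_references() if references is None else references)
    kind, sub, template = _resolve_mutation(mutation)
    reads: list[IndexedRead] = []
    planted = 0
    per_amplicon: dict[str, int] = {r.amplicon_id: 0 for r in refs}
    for i in range(n_reads):
        ref = refs[i % len(refs)]
        per_amplicon[ref.amplicon_id] += 1
        seq = ref.sequence
        is_mut = False
        if kind != "none" and fraction > 0:
            target_amp = sub.amplicon_id if sub is not None else "exon19"
            if ref.amplicon_id == target_amp and rng.random() < fraction:
                is_mut = True
                if kind == "substitution":
                    j = ref.index_of(sub.position)
                    seq = seq[:j] + sub.alt_base + seq[j + 1 :]
                else:
                    seq = template.sequence
        seq = _mutate_read(
            seq, rng, per_base_substitution_rate, per_base_indel_rate
        )
        planted += int(is_mut)
        reads.append(
            IndexedRead(
                read_id=f"read_{i:06d}",
                bases=index + seq,
                quality="I" * (len(seq) + len(index)),
            )
        )
    manifest = {
        "n_reads": n_reads,
        "index": index,
        "mutation": mutation,
        "fraction": fraction,
        "planted_mutant_reads": planted,
        "reads_per_amplicon": per_amplicon,
        "per_base_substitution_rate": per_base_substitution_rate,
        "per_base_indel_rate": per_base_indel_rate,
        "seed": seed,
    }
    return reads, manifest


def _mutate_read(
    seq: str,
    rng: np.random.Generator,
    sub_rate: float,
    indel_rate: float,
) -> str:
    if sub_rate <= 0 and indel_rate <= 0:
        return seq
    out = []
    for base in seq:
        u = rng.random()
        if u < indel_rate / 2:
            continue  # single-base deletion
        if u < indel_rate:
            out.append(str(rng.choice(list("ACGT"))))  # single-base insertion
            out.append(base)
            continue
        if u < indel_rate + sub_rate:
            out.append(str(rng.choice([b for b in "ACGT" if b != base])))
        else:
            out.append(base)
    return "".join(out)
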