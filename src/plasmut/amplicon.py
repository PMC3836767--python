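"""Amplicon references, read handling, alignment, and per-position counts.

Turns raw amplicon reads into the per-position base counts (pileups) and
exon-19 deletion-template assignments that the anomaly-detection caller
consumes.  Reads carry a 5-nt inline index for per-sample demultiplexing;
short reads (< 70 bases after index stripping) are discarded; reads are then
aligned glocally (read global, reference local) to the amplicon references
with affine gap scoring.

Exon-19 deletions are not read off the pileup — insertion/deletion read
errors are too frequent for that — but detected by matching reads against
eight template sequences carrying the common in-frame deletions, keeping the
template with the most assigned reads.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import Align

from .error_model import SubstitutionType

__all__ = [
    "INDEX_LENGTH",
    "MIN_READ_LENGTH",
    "DELETION_INTERVALS",
    "DELETION_LABEL",
    "TARGET_SUBSTITUTIONS",
    "SNP_EXCLUDED_LABELS",
    "AmpliconReference",
    "DeletionTemplate",
    "IndexedRead",
    "ReadAlignment",
    "PileupCounts",
    "default_references",
    "deletion_templates",
    "substitution_types",
    "demultiplex",
    "filter_short",
    "align_read",
    "build_pileup",
    "substitution_rate",
    "match_deletion_templates",
    "align_sample_reads",
    "deletion_fraction",
]

INDEX_LENGTH = 5
MIN_READ_LENGTH = 70

#: the eight common exon-19 in-frame deletions used for template matching:
#: (template_id, cDNA interval, GRCh37 chr7 interval), 1-based inclusive
DELETION_INTERVALS: tuple[tuple[str, tuple[int, int], tuple[int, int]], ...] = (
    ("del_2233_2247", (2233, 2247), (55242463, 55242477)),
    ("del_2235_2246", (2235, 2246), (55242465, 55242476)),
    ("del_2235_2249", (2235, 2249), (55242465, 55242479)),
    ("del_2236_2250", (2236, 2250), (55242466, 55242480)),
    ("del_2236_2256", (2236, 2256), (55242466, 55242486)),
    ("del_2238_2252", (2238, 2252), (55242468, 55242482)),
    ("del_2239_2247", (2239, 2247), (55242469, 55242477)),
    ("del_2239_2256", (2239, 2256), (55242469, 55242486)),
)

#: panel/report label of the exon-19 deletion channel (template-screen counts)
DELETION_LABEL = "exon19:2233:->del"


@dataclass(frozen=True)
class AmpliconReference:
    """One amplicon with its cDNA and genomic (GRCh37 chr7) coordinate frame.

    ``sequence`` indices map to coordinates through the start offsets:
    cDNA position p sits at sequence index p - cdna_start (EGFR is on the
    plus strand, so both maps are strictly increasing).  ``window`` is the
    1-based inclusive cDNA interval scored for errors and mutations; the
    union of the three default windows covers 169 base positions.
    """

    amplicon_id: str
    exon: int
    sequence: str
    cdna_start: int
    genomic_start: int
    window: tuple[int, int]

    def __post_init__(self) -> None:
        lo, hi = self.window
        if not (self.cdna_start <= lo <= hi <= self.cdna_end):
            raise ValueError("target window must lie within the amplicon sequence")

    @property
    def cdna_end(self) -> int:
        return self.cdna_start + len(self.sequence) - 1

    def index_of(self, cdna_pos: int) -> int:
        """0-based sequence index of a 1-based cDNA position."""
        if not (self.cdna_start <= cdna_pos <= self.cdna_end):
            raise ValueError(f"cDNA position {cdna_pos} outside {self.amplicon_id}")
        return cdna_pos - self.cdna_start

    def base_at(self, cdna_pos: int) -> str:
        return self.sequence[self.index_of(cdna_pos)]

    def genomic_of(self, cdna_pos: int) -> int:
        return self.genomic_start + (cdna_pos - self.cdna_start)

    @property
    def window_positions(self) -> range:
        return range(self.window[0], self.window[1] + 1)


@dataclass(frozen=True)
class DeletionTemplate:
    """Exon-19 reference with one deletion interval removed."""

    template_id: str
    cdna_interval: tuple[int, int]
    genomic_interval: tuple[int, int]
    sequence: str

    @property
    def deletion_length(self) -> int:
        return self.cdna_interval[1] - self.cdna_interval[0] + 1


def _synthetic_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


#: known target loci in the cDNA frame (NM_005228 numbering):
#: L858R c.2573T>G, L861Q c.2582T>A (exon 21); T790M c.2369C>T (exon 20);
#: the frequent SNP excluded from fitting is the G>A conversion at 2361.
_FIXED_BASES = {
    "exon20": {2361: "G", 2369: "C"},
    "exon21": {2573: "T", 2582: "T"},
}

_AMPLICON_LAYOUT = (
    # amplicon_id, exon, cdna_start, length, genomic_start, window
    ("exon19", 19, 2194, 97, 55242424, (2214, 2270)),
    ("exon20", 20, 2320, 96, 55249022, (2340, 2395)),
    ("exon21", 21, 2520, 96, 55259462, (2540, 2595)),
)


@lru_cache(maxsize=1)
def default_references() -> tuple[AmpliconReference, ...]:
    """The three EGFR amplicons (exons 19, 20, 21) used throughout.

    The coordinate frames (cDNA NM_005228 / genomic GRCh37 chr7 offsets,
    target loci, deletion intervals, SNP position) are the real ones; the
    base content between the pinned loci is synthetic — deterministic
    sequence generated in code, sufficient for error modeling and alignment
    but not the true EGFR sequence.  Windows span 57 + 56 + 56 = 169 base
    positions around the target loci.
    """
    rng = np.random.default_rng(20131121)
    refs = []
    for amp_id, exon, cdna_start, length, genomic_start, window in _AMPLICON_LAYOUT:
        seq = list(_synthetic_sequence(rng, length))
        for pos, base in _FIXED_BASES.get(amp_id, {}).items():
            seq[pos - cdna_start] = base
        refs.append(
            AmpliconReference(
                amplicon_id=amp_id,
                exon=exon,
                sequence="".join(seq),
                cdna_start=cdna_start,
                genomic_start=genomic_start,
                window=window,
            )
        )
    return tuple(refs)


def reference_map(
    references: Sequence[AmpliconReference] | None = None,
) -> dict[str, AmpliconReference]:
    refs = default_references() if references is None else references
    return {r.amplicon_id: r for r in refs}


def deletion_templates(
    exon19: AmpliconReference | None = None,
) -> tuple[DeletionTemplate, ...]:
    """Derive the eight deletion-template sequences from the exon-19 reference."""
    ref = exon19 if exon19 is not None else reference_map()["exon19"]
    templates = []
    for template_id, (lo, hi), genomic in DELETION_INTERVALS:
        i, j = ref.index_of(lo), ref.index_of(hi)
        templates.append(
            DeletionTemplate(
                template_id=template_id,
                cdna_interval=(lo, hi),
                genomic_interval=genomic,
                sequence=ref.sequence[:i] + ref.sequence[j + 1 :],
            )
        )
    return tuple(templates)


def _target_substitutions() -> dict[str, SubstitutionType]:
    refs = reference_map()
    return {
        "T790M": SubstitutionType("exon20", 2369, refs["exon20"].base_at(2369), "T"),
        "L858R": SubstitutionType("exon21", 2573, refs["exon21"].base_at(2573), "G"),
        "L861Q": SubstitutionType("exon21", 2582, refs["exon21"].base_at(2582), "A"),
    }


#: named target substitution loci (the exon-19 deletion is template-based)
TARGET_SUBSTITUTIONS: dict[str, SubstitutionType] = _target_substitutions()

#: default SNP exclusion: G>A at cDNA 2361 (frequent germline SNP)
SNP_EXCLUDED_LABELS: tuple[str, ...] = (
    SubstitutionType("exon20", 2361, "G", "A").label,
)


def substitution_types(
    reference: AmpliconReference, include_indel: bool = False
) -> list[SubstitutionType]:
    """All 3 substitution types per window position (plus the pooled indel
    pseudo-type per position when requested)."""
    out = []
    for pos in reference.window_positions:
        ref_base = reference.base_at(pos)
        for alt in "ACGT":
            if alt != ref_base:
                out.append(SubstitutionType(reference.amplicon_id, pos, ref_base, alt))
        if include_indel:
            out.append(SubstitutionType(reference.amplicon_id, pos, ref_base, "*"))
    return out


@dataclass(frozen=True)
class IndexedRead:
    """One sequencing read, possibly with its 5-nt index still attached."""

    read_id: str
    bases: str
    quality: str | None = None
    index: str | None = None
    sample: str | None = None

    def __post_init__(self) -> None:
        if self.index is not None and len(self.index) != INDEX_LENGTH:
            raise ValueError("inline indexes are 5 nt")

    def __len__(self) -> int:
        return len(self.bases)


def demultiplex(
    reads: Iterable[IndexedRead], index_table: Mapping[str, str]
) -> tuple[dict[str, list[IndexedRead]], int]:
    """Assign reads to samples by exact match of the first 5 bases.

    The index prefix is stripped from the assigned read.  Returns the
    per-sample read lists (every table sample present, possibly empty) and
    the number of discarded (unmatched) reads.
    """
    for key in index_table:
        if len(key) != INDEX_LENGTH:
            raise ValueError(f"index {key!r} is not {INDEX_LENGTH} nt")
    if len(set(index_table.values())) != len(index_table):
        # many-to-one index->sample is fine; duplicate *keys* cannot occur in
        # a dict, so only guard the documented misconfiguration explicitly
        pass
    by_sample: dict[str, list[IndexedRead]] = {s: [] for s in index_table.values()}
    discarded = 0
    for read in reads:
        prefix = read.bases[:INDEX_LENGTH]
        sample = index_table.get(prefix)
        if sample is None:
            discarded += 1
            continue
        qual = read.quality[INDEX_LENGTH:] if read.quality is not None else None
        by_sample[sample].append(
            replace(read, bases=read.bases[INDEX_LENGTH:], quality=qual,
                    index=prefix, sample=sample)
        )
    return by_sample, discarded


def filter_short(
    reads: Iterable[IndexedRead], min_length: int = MIN_READ_LENGTH
) -> list[IndexedRead]:
    """Discard reads shorter than ``min_length`` bases (post index-strip)."""
    return [r for r in reads if len(r) >= min_length]


@dataclass(frozen=True)
class ReadAlignment:
    """A glocal alignment of one read against one reference sequence.

    ``operations`` is a CIGAR-like list over the read in reference order:
    M (aligned base, match or mismatch), I (insertion in the read),
    D (deletion from the reference).  ``ref_start`` is the 0-based index of
    the first aligned reference base.
    """

    read_id: str
    reference_id: str
    ref_start: int
    operations: tuple[tuple[str, int], ...]
    read_bases: str
    score: float
    reverse: bool = False

    @property
    def ref_end(self) -> int:
        """0-based exclusive end on the reference."""
        return self.ref_start + sum(n for op, n in self.operations if op in "MD")


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -3.0
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -2.0
    # free end gaps on the reference side: read global, reference local
    aligner.open_end_deletion_score = 0.0
    aligner.extend_end_deletion_score = 0.0
    return aligner


_ALIGNER = _make_aligner()

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def alignment_score(read_bases: str, reference_sequence: str) -> float:
    """Score-only glocal alignment (fast path for reference selection)."""
    return float(_ALIGNER.score(reference_sequence, read_bases))


def _ops_from_biopython(alignment) -> tuple[int, tuple[tuple[str, int], ...]]:
    """Convert a Biopython alignment into (ref_start, CIGAR-like ops),
    clipping reference overhangs at both ends."""
    t_blocks, q_blocks = alignment.aligned
    ops: list[tuple[str, int]] = []
    ref_start = int(t_blocks[0][0])
    prev_t, prev_q = None, None
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        if prev_t is not None:
            dt, dq = ts - prev_t, qs - prev_q
            if dt:
                ops.append(("D", int(dt)))
            if dq:
                ops.append(("I", int(dq)))
        ops.append(("M", int(te - ts)))
        prev_t, prev_q = te, qe
    # merge adjacent same ops (D followed by another D cannot occur, M can)
    merged: list[tuple[str, int]] = []
    for op, n in ops:
        if merged and merged[-1][0] == op:
            merged[-1] = (op, merged[-1][1] + n)
        else:
            merged.append((op, n))
    return ref_start, tuple(merged)


def align_read(
    read: IndexedRead,
    reference: AmpliconReference | DeletionTemplate | str,
    min_score_frac: float = 0.25,
    try_reverse: bool = True,
) -> ReadAlignment | None:
    """Glocal affine-gap alignment of one read to one reference.

    Returns None (unaligned) when the best score falls below
    ``min_score_frac`` times the read length.  The reverse complement is
    tried as well; a reverse hit is used and flagged, since the amplicon
    protocol produces forward reads and reverse hits are worth logging.
    """
    if isinstance(reference, str):
        ref_id, ref_seq = "ref", reference
    elif isinstance(reference, DeletionTemplate):
        ref_id, ref_seq = reference.template_id, reference.sequence
    else:
        ref_id, ref_seq = reference.amplicon_id, reference.sequence
    if not ref_seq:
        raise ValueError("reference sequence must be non-empty")

    bases = read.bases
    score_f = alignment_score(bases, ref_seq)
    score, reverse = score_f, False
    if try_reverse:
        score_r = alignment_score(reverse_complement(bases), ref_seq)
        if score_r > score_f:
            score, reverse = score_r, True
            bases = reverse_complement(bases)
    if score < min_score_frac * len(read.bases):
        return None
    if reverse:
        warnings.warn(
            f"read {read.read_id} aligned in reverse orientation", stacklevel=2
        )
    alignment = _ALIGNER.align(ref_seq, bases)[0]
    ref_start, ops = _ops_from_biopython(alignment)
    return ReadAlignment(
        read_id=read.read_id,
        reference_id=ref_id,
        ref_start=ref_start,
        operations=ops,
        read_bases=bases,
        score=score,
        reverse=reverse,
    )


@dataclass
class PileupCounts:
    """Per-position base/indel counts over an amplicon's target window.

    ``depth`` at a position is the number of scored read observations
    (A/C/G/T bases plus spanning deletions); bases called N are excluded.
    Insertions are recorded at the window position immediately following the
    insertion point and pooled with deletions by :meth:`indel`, since the two
    error classes are not reliably distinguished by alignment.
    """

    amplicon_id: str
    positions: np.ndarray  # 1-based cDNA positions of the window
    base_counts: dict[str, np.ndarray]  # "A","C","G","T" -> counts
    deletions: np.ndarray
    insertions: np.ndarray
    n_reads: int = 0

    @classmethod
    def empty(cls, reference: AmpliconReference) -> "PileupCounts":
        n = len(reference.window_positions)
        return cls(
            amplicon_id=reference.amplicon_id,
            positions=np.array(list(reference.window_positions)),
            base_counts={b: np.zeros(n, dtype=np.int64) for b in "ACGT"},
            deletions=np.zeros(n, dtype=np.int64),
            insertions=np.zeros(n, dtype=np.int64),
        )

    def _idx(self, cdna_pos: int) -> int:
        i = int(cdna_pos - self.positions[0])
        if not (0 <= i < len(self.positions)):
            raise ValueError(f"position {cdna_pos} outside the target window")
        return i

    def depth_at(self, cdna_pos: int) -> int:
        i = self._idx(cdna_pos)
        return int(
            sum(self.base_counts[b][i] for b in "ACGT") + self.deletions[i]
        )

    @property
    def depth(self) -> np.ndarray:
        return (
            sum(self.base_counts[b] for b in "ACGT") + self.deletions
        ).astype(np.int64)

    def count_at(self, cdna_pos: int, base: str) -> int:
        return int(self.base_counts[base][self._idx(cdna_pos)])

    def indel(self, cdna_pos: int) -> int:
        """Pooled insertion + deletion events at a position."""
        i = self._idx(cdna_pos)
        return int(self.deletions[i] + self.insertions[i])


def build_pileup(
    alignments: Iterable[ReadAlignment], reference: AmpliconReference
) -> PileupCounts:
    """Tally per-position base, deletion, and insertion counts."""
    pile = PileupCounts.empty(reference)
    lo_idx = reference.index_of(reference.window[0])
    hi_idx = reference.index_of(reference.window[1])
    for aln in alignments:
        if aln.reference_id != reference.amplicon_id:
            raise ValueError(
                f"alignment to {aln.reference_id!r} mixed into {reference.amplicon_id!r} pileup"
            )
        pile.n_reads += 1
        rpos = aln.ref_start
        qpos = 0
        for op, n in aln.operations:
            if op == "M":
                for k in range(n):
                    i = rpos + k
                    if lo_idx <= i <= hi_idx:
                        base = aln.read_bases[qpos + k]
                        if base in "ACGT":  # N never counts toward depth
                            pile.base_counts[base][i - lo_idx] += 1
                rpos += n
                qpos += n
            elif op == "D":
                for k in range(n):
                    i = rpos + k
                    if lo_idx <= i <= hi_idx:
                        pile.deletions[i - lo_idx] += 1
                rpos += n
            elif op == "I":
                if lo_idx <= rpos <= hi_idx:
                    pile.insertions[rpos - lo_idx] += 1
                qpos += n
            else:  # pragma: no cover - defensive
                raise ValueError(f"unknown alignment operation {op!r}")
    return pile


def substitution_rate(pileup: PileupCounts, sub_type: SubstitutionType) -> float:
    """Fraction of reads carrying the alternate base at the position:
    alt count divided by all scored base counts there."""
    depth = pileup.depth_at(sub_type.position)
    if depth == 0:
        raise ZeroDivisionError(
            f"no coverage at {sub_type.label}; rate undefined"
        )
    if sub_type.is_indel:
        return pileup.indel(sub_type.position) / depth
    return pileup.count_at(sub_type.position, sub_type.alt_base) / depth


def match_deletion_templates(
    reads: Iterable[IndexedRead],
    intact_reference: AmpliconReference,
    templates: Sequence[DeletionTemplate],
) -> tuple[dict[str, int], int, str | None]:
    """Assign each exon-19 read to the best-scoring sequence among the
    intact reference and the deletion templates.

    Returns (per-template read counts, intact read count, chosen template id).
    The chosen template is the one with the most assigned reads; ties break
    to the lexicographically smallest template id; score ties for a single
    read favour the intact reference (conservative).  Returns None as the
    chosen template when no read matched any template.
    """
    if not templates:
        raise ValueError("at least one deletion template is required")
    counts = {t.template_id: 0 for t in templates}
    intact_count = 0
    candidates = [("", intact_reference.sequence)] + [
        (t.template_id, t.sequence) for t in sorted(templates, key=lambda t: t.template_id)
    ]
    for read in reads:
        best_id, best_score = "", -np.inf
        for cand_id, seq in candidates:
            s = alignment_score(read.bases, seq)
            if s > best_score:
                best_id, best_score = cand_id, s
        if best_id:
            counts[best_id] += 1
        else:
            intact_count += 1
    total_templated = sum(counts.values())
    if total_templated == 0:
        return counts, intact_count, None
    chosen = min(counts, key=lambda tid: (-counts[tid], tid))
    return counts, intact_count, chosen


def align_sample_reads(
    reads: Sequence[IndexedRead],
    references: Sequence[AmpliconReference] | None = None,
) -> tuple[dict[str, PileupCounts], dict[str, int], int]:
    """One sample's full counting path: amplicon assignment, alignment,
    pileups, and the exon-19 deletion-template screen.

    Each read is assigned to its best-scoring amplicon; exon-19 reads go
    through template matching (intact vs the eight deletion templates)
    before contributing to the exon-19 pileup.  Returns (pileups by
    amplicon, deletion-template read counts, total exon-19 reads).
    """
    refs = reference_map(references)
    templates = deletion_templates(refs.get("exon19"))
    by_amp: dict[str, list[ReadAlignment]] = {amp: [] for amp in refs}
    exon19_reads: list[IndexedRead] = []
    for read in reads:
        scores = {amp: alignment_score(read.bases, r.sequence) for amp, r in refs.items()}
        best = max(sorted(scores), key=lambda a: scores[a])
        if best == "exon19":
            exon19_reads.append(read)
        else:
            aln = align_read(read, refs[best])
            if aln is not None:
                by_amp[best].append(aln)
    template_counts, intact_count, _ = match_deletion_templates(
        exon19_reads, refs["exon19"], templates
    )
    for read in exon19_reads:
        aln = align_read(read, refs["exon19"])
        if aln is not None:
            by_amp["exon19"].append(aln)
    exon19_total = intact_count + sum(template_counts.values())
    pileups = {amp: build_pileup(alns, refs[amp]) for amp, alns in by_amp.items()}
    return pileups, template_counts, exon19_total


def deletion_fraction(
    template_counts: Mapping[str, int],
    exon19_total: int,
    numerator: str = "chosen",
) -> float:
    """Deletion mutant fraction: deletion-type reads over all exon-19 reads.

    ``numerator="chosen"`` (default) counts only the template with the most
    reads, the convention used for frequency estimation; ``"sum"`` counts
    reads over all templates.
    """
    if exon19_total <= 0:
        raise ZeroDivisionError("no exon-19 aligned reads; fraction undefined")
    if numerator not in ("chosen", "sum"):
        raise ValueError("numerator must be 'chosen' or 'sum'")
    if not template_counts:
        return 0.0
    if numerator == "sum":
        num = sum(template_counts.values())
    else:
        num = max(template_counts.values())
    return num / exon19_total
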