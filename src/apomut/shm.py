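"""Somatic-hypermutation spectrum analysis.

Pipeline for Sanger-style, pre-aligned clone sequences of a selection-
neutral readout region (e.g. the J_H4 intron downstream of a rearranged
heavy-chain VDJ exon): mutation calling against the germline reference,
exclusion filtering and clonal deduplication, construction of the 12-class
substitution spectrum with base-composition correction, mutation frequency,
tandem and positional statistics, and χ²-based strand-bias testing.

Conventions: coordinates are 0-based, half-open; substitutions are always
reported on the top (sense/+) strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .simulator import BASES, SUBSTITUTION_CLASSES

__all__ = [
    "Reference",
    "CloneObservation",
    "MutationCall",
    "SubstitutionSpectrum",
    "StrandBiasResult",
    "call_mutations",
    "filter_and_dedupe",
    "build_spectrum",
    "mutation_frequency",
    "positional_distribution",
    "strand_bias_test",
    "compare_spectra",
]

GAP_SYMBOLS = set("-.")
# IUPAC ambiguity codes treated as no-call at that position
AMBIGUITY_CODES = set("NRYSWKMBDHV")


@dataclass(frozen=True)
class Reference:
    """Germline reference with the analysed window.

    ``analysis_window`` and ``cdr3_window`` are 0-based half-open intervals
    on ``sequence``; the CDR3 window (used only as a clonal identifier) may
    be empty.
    """

    id: str
    sequence: str
    analysis_window: tuple[int, int] | None = None
    cdr3_window: tuple[int, int] = (0, 0)

    def __post_init__(self):
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if not seq:
            raise ValueError("reference sequence is empty")
        bad = set(seq) - set(BASES)
        if bad:
            raise ValueError(f"reference contains non-ACGT symbols: {sorted(bad)}")
        if self.analysis_window is None:
            object.__setattr__(self, "analysis_window", (0, len(seq)))
        for name in ("analysis_window", "cdr3_window"):
            lo, hi = getattr(self, name)
            if not (0 <= lo <= hi <= len(seq)):
                raise ValueError(f"{name} {(lo, hi)} outside sequence of length {len(seq)}")

    @property
    def base_counts(self) -> dict[str, int]:
        """Count of each base within the analysis window."""
        lo, hi = self.analysis_window
        window = self.sequence[lo:hi]
        return {b: window.count(b) for b in BASES}


@dataclass(frozen=True)
class CloneObservation:
    """One aligned clone sequence (same length as the reference)."""

    clone_id: str
    sample_id: str
    sequence: str

    def __post_init__(self):
        object.__setattr__(self, "sequence", self.sequence.upper())

    def cdr3_key(self, reference: Reference) -> str:
        lo, hi = reference.cdr3_window
        return self.sequence[lo:hi]


@dataclass(frozen=True)
class MutationCall:
    """One substitution call on the top strand (0-based position)."""

    clone_id: str
    position: int
    ref_base: str
    alt_base: str

    def __post_init__(self):
        if self.ref_base == self.alt_base:
            raise ValueError("ref_base equals alt_base")

    @property
    def substitution(self) -> str:
        return f"{self.ref_base}>{self.alt_base}"


@dataclass
class SubstitutionSpectrum:
    """12-class substitution counts with composition-corrected percentages.

    ``total_sequenced_bases[X]`` is the per-base denominator: the number of
    unambiguously read reference-``X`` positions summed over the counted
    sequences (``N_X × n_sequences`` when every position is read).
    ``corrected_percent`` re-weights each class by its denominator, which is
    equivalent to forcing each base to contribute 25% of the sequence.
    """

    counts: dict[str, int]
    total_sequenced_bases: dict[str, int]
    n_sequences: int
    n_tandems: int
    raw_percent: dict[str, float] = field(init=False)
    corrected_percent: dict[str, float] = field(init=False)

    def __post_init__(self):
        total = sum(self.counts.values())
        if total <= 0:
            raise ValueError("spectrum requires at least one mutation")
        self.raw_percent = {c: 100.0 * self.counts[c] / total for c in SUBSTITUTION_CLASSES}
        weights = {}
        for cls in SUBSTITUTION_CLASSES:
            ref_base = cls[0]
            denom = self.total_sequenced_bases[ref_base]
            weights[cls] = self.counts[cls] / denom if denom else 0.0
        w_sum = sum(weights.values())
        self.corrected_percent = {c: 100.0 * weights[c] / w_sum for c in SUBSTITUTION_CLASSES}

    @property
    def n_mutations(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class StrandBiasResult:
    """G>C versus C>G transversion bias with its χ² test."""

    count_GtoC: int
    count_CtoG: int
    ratio: float
    chi2_statistic: float
    p_value: float
    table_construction: str  # "pair_only" | "vs_sequenced"


def call_mutations(
    reference: Reference, clone: CloneObservation
) -> tuple[list[MutationCall], bool]:
    """Call substitutions of a clone against the reference.

    Positions are restricted to the analysis window. Gap symbols set the
    indel flag and produce no substitution call; IUPAC ambiguity codes
    (including N) are no-calls. Returns (calls, indel_flag).
    """
    if len(clone.sequence) != len(reference.sequence):
        raise ValueError(
            f"clone {clone.clone_id!r} length {len(clone.sequence)} != "
            f"reference length {len(reference.sequence)}"
        )
    allowed = set(BASES) | GAP_SYMBOLS | AMBIGUITY_CODES
    lo, hi = reference.analysis_window
    calls: list[MutationCall] = []
    indel = False
    for pos in range(lo, hi):
        base = clone.sequence[pos]
        if base not in allowed:
            raise ValueError(
                f"clone {clone.clone_id!r} has non-IUPAC symbol {base!r} at position {pos}"
            )
        if base in GAP_SYMBOLS:
            indel = True
            continue
        if base in AMBIGUITY_CODES:
            continue
        ref_base = reference.sequence[pos]
        if base != ref_base:
            calls.append(MutationCall(clone.clone_id, pos, ref_base, base))
    return calls, indel


def filter_and_dedupe(
    reference: Reference,
    clones: Sequence[CloneObservation],
) -> tuple[list[CloneObservation], dict[str, list[MutationCall]], list[dict]]:
    """Apply the exclusion and clonal-deduplication rules.

    Excluded: unmutated clones; clones containing insertions/deletions
    (gap symbols) — removed from both counts and denominators; within a
    sample, clones with identical mutation sets and identical CDR3 are
    counted once (the lexicographically smallest clone_id is retained), as
    are exact duplicate sequences.

    Returns (retained clones, calls per retained clone_id, exclusion log);
    each log entry records ``clone_id``, ``rule`` and, for clonal
    collapses, the retained ``representative``.
    """
    log: list[dict] = []
    calls_by_id: dict[str, list[MutationCall]] = {}
    survivors: list[CloneObservation] = []
    for clone in clones:
        calls, indel = call_mutations(reference, clone)
        if indel:
            log.append({"clone_id": clone.clone_id, "rule": "indel", "representative": ""})
            continue
        if not calls:
            log.append({"clone_id": clone.clone_id, "rule": "unmutated", "representative": ""})
            continue
        calls_by_id[clone.clone_id] = calls
        survivors.append(clone)

    # clonal dedup: within a sample, identical mutation sets + identical CDR3
    # collapse to one representative; identical full sequences are a special
    # case of the same key set and collapse with it.
    groups: dict[tuple, list[CloneObservation]] = {}
    for clone in survivors:
        key_calls = frozenset(
            (c.position, c.ref_base, c.alt_base) for c in calls_by_id[clone.clone_id]
        )
        key = (clone.sample_id, key_calls, clone.cdr3_key(reference))
        groups.setdefault(key, []).append(clone)

    retained: list[CloneObservation] = []
    for members in groups.values():
        members = sorted(members, key=lambda c: c.clone_id)
        keep = members[0]
        retained.append(keep)
        for dup in members[1:]:
            rule = (
                "duplicate_sequence"
                if dup.sequence == keep.sequence
                else "clonal_duplicate"
            )
            log.append(
                {"clone_id": dup.clone_id, "rule": rule, "representative": keep.clone_id}
            )
            calls_by_id.pop(dup.clone_id, None)
    retained.sort(key=lambda c: c.clone_id)
    return retained, calls_by_id, log


def _sequenced_base_totals(
    reference: Reference, clones: Sequence[CloneObservation]
) -> dict[str, int]:
    """Per-base denominators: reference-base counts over unambiguously
    read window positions, summed over clones."""
    lo, hi = reference.analysis_window
    totals = {b: 0 for b in BASES}
    for clone in clones:
        for pos in range(lo, hi):
            if clone.sequence[pos] in AMBIGUITY_CODES:
                continue
            totals[reference.sequence[pos]] += 1
    return totals


def build_spectrum(
    reference: Reference,
    retained: Sequence[CloneObservation],
    calls_by_id: dict[str, list[MutationCall]],
) -> SubstitutionSpectrum:
    """Sum the 12-class substitution counts over the retained clones.

    A tandem mutation is a pair of substitutions at immediately adjacent
    positions (p, p+1) within one clone.
    """
    if not retained:
        raise ValueError("no retained clones: spectrum is undefined")
    counts = {cls: 0 for cls in SUBSTITUTION_CLASSES}
    n_tandems = 0
    for clone in retained:
        calls = calls_by_id.get(clone.clone_id, [])
        for call in calls:
            counts[call.substitution] += 1
        positions = sorted(c.position for c in calls)
        n_tandems += sum(
            1 for a, b in zip(positions, positions[1:]) if b == a + 1
        )
    return SubstitutionSpectrum(
        counts=counts,
        total_sequenced_bases=_sequenced_base_totals(reference, retained),
        n_sequences=len(retained),
        n_tandems=n_tandems,
    )


def mutation_frequency(n_mutations: int, n_sequenced_bp: int) -> float:
    """Overall mutation frequency as a percentage, to 2 decimals.

    100 × mutations / sequenced base pairs (e.g. 773 in 68 770 bp → 1.12).
    """
    if n_sequenced_bp <= 0:
        raise ValueError("n_sequenced_bp must be positive")
    return round(100.0 * n_mutations / n_sequenced_bp, 2)


def positional_distribution(
    reference: Reference,
    retained: Sequence[CloneObservation],
    calls_by_id: dict[str, list[MutationCall]],
) -> np.ndarray:
    """Percentage of mutated sequences carrying a mutation at each window
    position (length = window length; index 0 = window start)."""
    if not retained:
        raise ValueError("no retained clones")
    lo, hi = reference.analysis_window
    tally = np.zeros(hi - lo, dtype=float)
    for clone in retained:
        hit = {c.position for c in calls_by_id.get(clone.clone_id, [])}
        for pos in hit:
            tally[pos - lo] += 1
    return 100.0 * tally / len(retained)


def _pearson_chi2_2x2(table: np.ndarray) -> tuple[float, float]:
    """1-df Pearson χ² on a 2×2 table, no continuity correction."""
    chi2, p, dof, _ = stats.chi2_contingency(table, correction=False)
    assert dof == 1
    return float(chi2), float(p)


def strand_bias_test(
    spectrum: SubstitutionSpectrum,
    construction: str = "vs_sequenced",
) -> StrandBiasResult:
    """Test the G>C versus C>G transversion asymmetry.

    ``construction="pair_only"``: 1-df goodness-of-fit of the two counts
    against equal expectation, χ² = (a−b)²/(a+b). ``"vs_sequenced"``
    (default): 1-df Pearson χ² on the 2×2 table of mutated versus sequenced
    G and C bases. No continuity correction in either case.
    """
    a = spectrum.counts["G>C"]
    b = spectrum.counts["C>G"]
    if a == 0 and b == 0:
        raise ValueError("both G>C and C>G counts are zero; bias is undefined")
    ratio = a / b if b else float("inf")
    if construction == "pair_only":
        chi2 = (a - b) ** 2 / (a + b)
        p = float(stats.chi2.sf(chi2, df=1))
    elif construction == "vs_sequenced":
        n_g = spectrum.total_sequenced_bases["G"]
        n_c = spectrum.total_sequenced_bases["C"]
        table = np.array([[a, n_g - a], [b, n_c - b]], dtype=float)
        chi2, p = _pearson_chi2_2x2(table)
    else:
        raise ValueError(f"unknown construction {construction!r}")
    return StrandBiasResult(
        count_GtoC=a,
        count_CtoG=b,
        ratio=ratio,
        chi2_statistic=float(chi2),
        p_value=p,
        table_construction=construction,
    )


def compare_spectra(
    spectrum_a: SubstitutionSpectrum,
    spectrum_b: SubstitutionSpectrum,
    substitution_class: str,
) -> tuple[float, float]:
    """χ² comparison of one substitution class between two spectra.

    1-df Pearson χ² (no continuity correction) on the 2×2 table of mutated
    versus sequenced bases of the class's reference base in each cohort.
    Returns (chi2, p).
    """
    if substitution_class not in SUBSTITUTION_CLASSES:
        raise ValueError(f"unknown substitution class {substitution_class!r}")
    ref_base = substitution_class[0]
    rows = []
    for sp in (spectrum_a, spectrum_b):
        m = sp.counts[substitution_class]
        n = sp.total_sequenced_bases[ref_base]
        if n <= 0:
            raise ValueError(f"zero sequenced {ref_base} bases in one spectrum")
        rows.append([m, n - m])
    table = np.array(rows, dtype=float)
    if table[:, 0].sum() == 0:
        return 0.0, 1.0
    return _pearson_chi2_2x2(table)


def spectrum_from_events(events: Iterable) -> dict[str, int]:
    """Tally simulator events into 12-class counts (mutagenic events only)."""
    counts = {cls: 0 for cls in SUBSTITUTION_CLASSES}
    for e in events:
        if e.resulting_substitution is not None:
            counts[e.resulting_substitution] += 1
    return counts
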