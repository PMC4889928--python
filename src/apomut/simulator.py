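"""Stochastic simulator of strand-biased damage tolerance at AP-sites.

The model follows the fate of a deaminated cytosine (C→U) on either strand
of a double-stranded reference during one round of replication:

1. With probability ``1 - p_ap`` the uracil is replicated over: an A is
   inserted opposite the template U, fixing a C>T transition on the
   lesion-bearing strand.
2. Otherwise the U is excised, leaving an abasic (AP) site. If the lesion
   strand serves as the template for leading-strand synthesis, the fork can
   reprime downstream with probability ``p_reprime`` and the gap is repaired
   error-free. Repriming on the lagging-strand template is assumed to be
   unnecessary (Okazaki priming restarts synthesis anyway) and is fixed at 0.
3. An unrescued AP-site is bypassed by error-prone translesion synthesis,
   which inserts a base drawn from ``tls_insertion`` opposite the lesion:
   an inserted A fixes C>T, C fixes C>G, T fixes C>A, and G restores the
   original pair (no mutation).

Lesions on the bottom strand are reported on the top strand as G>A / G>C /
G>T. Because only the leading-strand template is eligible for repriming,
``p_reprime > 0`` produces the characteristic asymmetry between C>G and G>C
transversions.

The module also provides the closed-form expectation of the per-class
mutation counts (used as an oracle against the Monte-Carlo path) and a
moment estimator that inverts the closed form to recover ``p_reprime`` from
an observed spectrum.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "SimConfig",
    "SimEvent",
    "SUBSTITUTION_CLASSES",
    "simulate_clones",
    "expected_substitution_rates",
    "recover_reprime_probability",
    "tpc_motif_weights",
    "wrc_motif_weights",
]

BASES = ("A", "C", "G", "T")
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: the 12 ordered top-strand substitution classes
SUBSTITUTION_CLASSES = tuple(
    f"{x}>{y}" for x in BASES for y in BASES if x != y
)

# base inserted by TLS opposite the AP-site -> new base on the lesion strand
_TLS_OUTCOME = {"A": "T", "C": "G", "T": "A", "G": "C"}  # G restores C (no mutation)


def tpc_motif_weights(fold: float = 10.0) -> dict[str, float]:
    """Motif weights for a TpC-preferring deaminase (APOBEC3A/B-like).

    Every 3-mer whose 5' neighbour on the C-bearing strand is T gets weight
    ``fold``; all others weight 1.
    """
    return {
        f"{n5}C{n3}": (fold if n5 == "T" else 1.0)
        for n5 in BASES
        for n3 in BASES
    }


def wrc_motif_weights(fold: float = 10.0) -> dict[str, float]:
    """Motif weights for a WRC-preferring deaminase (AID-like hotspots).

    W = A/T two bases 5' is not visible in a 3-mer window, so the preset
    up-weights R (A/G) immediately 5' of the C.
    """
    return {
        f"{n5}C{n3}": (fold if n5 in "AG" else 1.0)
        for n5 in BASES
        for n3 in BASES
    }


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the deamination / AP-site damage-tolerance model.

    Parameters
    ----------
    deamination_rate
        Probability that any given eligible C (on either strand) is
        deaminated, per clone. Multiplied by the site's motif weight.
    motif_weights
        Map from 3-mer context read on the C-bearing strand (5'N, C, 3'N)
        to a nonnegative multiplier. Missing 3-mers, and edge positions
        lacking a flank, use the multiplier 1.0.
    p_ap
        Probability a uracil is processed to an AP-site before replication
        (otherwise it is replicated over, fixing a C>T transition).
    p_reprime
        Probability an AP-site on the *leading-strand template* is resolved
        error-free by repriming plus gap repair. Lagging-template AP-sites
        are never reprimed in this model.
    tls_insertion
        Distribution over the base inserted opposite an AP-site by TLS.
        Must sum to 1.
    leading_template_strand
        Which strand of the reference templates leading-strand synthesis
        ("top" or "bottom"); determined by the replication-origin side.
    n_clones
        Number of independent clone sequences to generate.
    seed
        RNG seed; identical configs produce byte-identical output.
    at_collateral_rate
        Optional flat per-A/T-base substitution probability modelling
        mismatch-repair-driven collateral mutagenesis around U/G mismatches
        (uniform over the three alternative bases). Default 0 (off).
    """

    deamination_rate: float = 0.02
    motif_weights: Mapping[str, float] = field(default_factory=dict)
    p_ap: float = 0.5
    p_reprime: float = 0.0
    tls_insertion: Mapping[str, float] = field(
        default_factory=lambda: {"A": 0.25, "C": 0.25, "G": 0.25, "T": 0.25}
    )
    leading_template_strand: str = "top"
    n_clones: int = 1
    seed: int = 0
    at_collateral_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in ("deamination_rate", "p_ap", "p_reprime", "at_collateral_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v!r}")
        if self.leading_template_strand not in ("top", "bottom"):
            raise ValueError(
                "leading_template_strand must be 'top' or 'bottom', "
                f"got {self.leading_template_strand!r}"
            )
        if self.n_clones < 1:
            raise ValueError(f"n_clones must be >= 1, got {self.n_clones}")
        if set(self.tls_insertion) != set(BASES):
            raise ValueError("tls_insertion must give a probability for each of A/C/G/T")
        total = sum(self.tls_insertion.values())
        if any(p < 0 for p in self.tls_insertion.values()) or abs(total - 1.0) > 1e-12:
            raise ValueError(f"tls_insertion must be a distribution summing to 1, sums to {total}")
        for motif, w in self.motif_weights.items():
            if w < 0:
                raise ValueError(f"motif_weights[{motif!r}] must be >= 0, got {w}")

    def replace(self, **kwargs) -> "SimConfig":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class SimEvent:
    """One lesion and its fate in one clone.

    ``position`` is the 0-based index on the top strand. ``lesion_strand``
    is the strand carrying the deaminated C. ``resulting_substitution`` is
    reported on the top strand ("C>T", "G>A", ...) or ``None`` when the
    lesion was resolved without a mutation.
    """

    clone_id: str
    position: int
    lesion_strand: str  # "top" | "bottom"
    fate: str  # "replicated_over_U" | "ap_reprimed" | "ap_tls" | "at_collateral"
    inserted_base: str | None
    resulting_substitution: str | None


def _site_weights(sequence: str, motif_weights: Mapping[str, float]):
    """Eligible C sites on both strands with their motif multipliers.

    Returns (positions, strands, weights) arrays. A top-strand G is a
    bottom-strand C; its context is read on the bottom strand (reverse
    complement). Edge positions lacking a flank get weight 1.0.
    """
    positions, strands, weights = [], [], []
    n = len(sequence)
    for i, base in enumerate(sequence):
        if base == "C":
            strand = "top"
        elif base == "G":
            strand = "bottom"
        else:
            continue
        if i == 0 or i == n - 1:
            w = 1.0
        else:
            if strand == "top":
                motif = sequence[i - 1] + "C" + sequence[i + 1]
            else:
                motif = COMPLEMENT[sequence[i + 1]] + "C" + COMPLEMENT[sequence[i - 1]]
            w = float(motif_weights.get(motif, 1.0))
        positions.append(i)
        strands.append(strand)
        weights.append(w)
    return (
        np.asarray(positions, dtype=np.int64),
        np.asarray(strands, dtype=object),
        np.asarray(weights, dtype=float),
    )


def _validate_reference_sequence(sequence: str) -> str:
    sequence = sequence.upper()
    if not sequence:
        raise ValueError("reference sequence is empty")
    bad = set(sequence) - set(BASES)
    if bad:
        raise ValueError(f"reference contains non-ACGT symbols: {sorted(bad)}")
    return sequence


def _report_on_top(lesion_strand: str, new_base_on_lesion_strand: str) -> str | None:
    """Top-strand substitution string for a lesion-strand base change."""
    if new_base_on_lesion_strand == "C":
        return None
    if lesion_strand == "top":
        return f"C>{new_base_on_lesion_strand}"
    return f"G>{COMPLEMENT[new_base_on_lesion_strand]}"


def simulate_clones(reference, config: SimConfig):
    """Generate mutated clone sequences and the per-lesion event trace.

    ``reference`` may be a plain A/C/G/T string or any object with a
    ``sequence`` attribute (e.g. :class:`apomut.shm.Reference`).

    Returns
    -------
    (clones, events)
        ``clones`` is a list of ``n_clones`` sequences (same length as the
        reference); ``events`` a list of :class:`SimEvent`, one per lesion,
        in (clone, position) order. Every difference between a clone and
        the reference is explained by exactly one event with a non-``None``
        ``resulting_substitution``; at most one lesion per site per clone.
    """
    sequence = _validate_reference_sequence(
        reference if isinstance(reference, str) else reference.sequence
    )
    rng = np.random.default_rng(config.seed)
    positions, strands, weights = _site_weights(sequence, config.motif_weights)

    p_lesion = config.deamination_rate * weights
    if np.any(p_lesion > 1.0):
        raise ValueError(
            "deamination_rate times motif weight exceeds 1 at some site; "
            "lower the rate or the weights"
        )

    n_clones, n_sites = config.n_clones, len(positions)
    clones: list[str] = []
    events: list[SimEvent] = []

    # Draw order: one clone-major Bernoulli matrix over eligible C sites,
    # then per lesion (clone-major, left-to-right) three uniforms: AP vs
    # replication-over, reprime, TLS base choice. All three are drawn for
    # every lesion regardless of branch so the stream stays aligned.
    if n_sites:
        lesion_matrix = rng.random((n_clones, n_sites)) < p_lesion[None, :]
    else:
        lesion_matrix = np.zeros((n_clones, 0), dtype=bool)
    clone_idx, site_idx = np.nonzero(lesion_matrix)
    n_lesions = len(clone_idx)
    u_ap = rng.random(n_lesions)
    u_reprime = rng.random(n_lesions)
    u_tls = rng.random(n_lesions)

    tls_bases = np.array(BASES)
    tls_probs = np.array([config.tls_insertion[b] for b in BASES], dtype=float)
    tls_cum = np.cumsum(tls_probs)

    seq_arrays = {k: list(sequence) for k in range(n_clones)}
    width = len(str(max(n_clones - 1, 0)))
    clone_ids = [f"clone_{k:0{width}d}" for k in range(n_clones)]

    for j in range(n_lesions):
        k = int(clone_idx[j])
        s = int(site_idx[j])
        pos = int(positions[s])
        strand = strands[s]
        on_leading = strand == config.leading_template_strand
        inserted: str | None = None
        if u_ap[j] >= config.p_ap:
            fate = "replicated_over_U"
            new_base = "T"  # U read as T on the lesion strand
        elif on_leading and u_reprime[j] < config.p_reprime:
            fate = "ap_reprimed"
            new_base = "C"
        else:
            fate = "ap_tls"
            inserted = str(tls_bases[np.searchsorted(tls_cum, u_tls[j], side="right")])
            new_base = _TLS_OUTCOME[inserted]
        substitution = _report_on_top(strand, new_base)
        if substitution is not None:
            alt_top = substitution.split(">")[1]
            seq_arrays[k][pos] = alt_top
        events.append(
            SimEvent(
                clone_id=clone_ids[k],
                position=pos,
                lesion_strand=strand,
                fate=fate,
                inserted_base=inserted,
                resulting_substitution=substitution,
            )
        )

    if config.at_collateral_rate > 0:
        at_positions = np.asarray(
            [i for i, b in enumerate(sequence) if b in "AT"], dtype=np.int64
        )
        if len(at_positions):
            hit = rng.random((n_clones, len(at_positions))) < config.at_collateral_rate
            pick = rng.integers(0, 3, size=hit.shape)
            for k, s in zip(*np.nonzero(hit)):
                pos = int(at_positions[s])
                ref_base = sequence[pos]
                alts = [b for b in BASES if b != ref_base]
                alt = alts[int(pick[k, s])]
                seq_arrays[int(k)][pos] = alt
                events.append(
                    SimEvent(
                        clone_id=clone_ids[int(k)],
                        position=pos,
                        lesion_strand="top",
                        fate="at_collateral",
                        inserted_base=None,
                        resulting_substitution=f"{ref_base}>{alt}",
                    )
                )
            events.sort(key=lambda e: (e.clone_id, e.position))

    clones = ["".join(seq_arrays[k]) for k in range(n_clones)]
    return clones, events


def expected_substitution_rates(config: SimConfig, reference) -> dict[str, float]:
    """Closed-form expected per-clone count of each substitution class.

    For a top-strand C at a site of weight ``w`` (``d`` the deamination
    rate, ``π`` the TLS insertion distribution, ``r`` the effective
    repriming probability on that strand's template role)::

        E[C>T] = d·w·[(1 − p_ap) + p_ap·(1 − r)·π_A]
        E[C>G] = d·w·p_ap·(1 − r)·π_C
        E[C>A] = d·w·p_ap·(1 − r)·π_T

    and symmetrically for bottom-strand Cs reported as G>A / G>C / G>T.
    Totals sum over sites. The optional A/T collateral rate contributes
    ``rate/3`` per A or T site to each of its three classes.
    """
    sequence = _validate_reference_sequence(
        reference if isinstance(reference, str) else reference.sequence
    )
    _, strands, weights = _site_weights(sequence, config.motif_weights)
    d = config.deamination_rate
    pi = config.tls_insertion
    expected = {cls: 0.0 for cls in SUBSTITUTION_CLASSES}

    for strand in ("top", "bottom"):
        w_total = float(weights[strands == strand].sum())
        r = config.p_reprime if strand == config.leading_template_strand else 0.0
        base = d * w_total
        e_ct = base * ((1 - config.p_ap) + config.p_ap * (1 - r) * pi["A"])
        e_cg = base * config.p_ap * (1 - r) * pi["C"]
        e_ca = base * config.p_ap * (1 - r) * pi["T"]
        if strand == "top":
            expected["C>T"] += e_ct
            expected["C>G"] += e_cg
            expected["C>A"] += e_ca
        else:
            expected["G>A"] += e_ct
            expected["G>C"] += e_cg
            expected["G>T"] += e_ca

    if config.at_collateral_rate > 0:
        n_a = sequence.count("A")
        n_t = sequence.count("T")
        per = config.at_collateral_rate / 3.0
        for alt in "CGT":
            expected[f"A>{alt}"] += n_a * per
        for alt in "ACG":
            expected[f"T>{alt}"] += n_t * per
    return expected


def recover_reprime_probability(spectrum) -> float:
    """Moment estimate of the leading-strand repriming probability.

    Inverts the closed-form expectation ratio E[C>G]/E[G>C] = 1 − p_reprime
    (valid only under symmetric deamination of the two strands, a top
    leading-strand template, and no lagging-strand repriming), returning
    ``1 − M[C>G]/M[G>C]`` clamped to [0, 1].

    ``spectrum`` may be a mapping of class counts or an object with a
    ``counts`` mapping (e.g. :class:`apomut.shm.SubstitutionSpectrum`).
    """
    counts = spectrum if isinstance(spectrum, Mapping) else spectrum.counts
    g_to_c = counts["G>C"]
    c_to_g = counts["C>G"]
    if g_to_c == 0:
        raise ValueError("repriming probability is undefined when the G>C count is 0")
    return min(1.0, max(0.0, 1.0 - c_to_g / g_to_c))


def write_clone_fasta(clones: Iterable[str], path) -> None:
    """Write clone sequences as FASTA with headers ``clone_<k>``."""
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    clones = list(clones)
    width = len(str(max(len(clones) - 1, 0)))
    records = [
        SeqRecord(Seq(s), id=f"clone_{k:0{width}d}", description="")
        for k, s in enumerate(clones)
    ]
    SeqIO.write(records, str(path), "fasta")


def write_event_trace(events: Iterable[SimEvent], path, reference=None) -> None:
    """Write the event trace as TSV.

    Columns: clone_id, position (0-based, top strand), lesion_strand, fate,
    inserted_base, ref, alt (top strand; '.' when no mutation resulted).
    """
    import pandas as pd

    rows = []
    for e in events:
        if e.resulting_substitution is not None:
            ref_b, alt_b = e.resulting_substitution.split(">")
        else:
            ref_b = "C" if e.lesion_strand == "top" else "G"
            alt_b = "."
        rows.append(
            {
                "clone_id": e.clone_id,
                "position": e.position,
                "lesion_strand": e.lesion_strand,
                "fate": e.fate,
                "inserted_base": e.inserted_base or ".",
                "ref": ref_b,
                "alt": alt_b,
            }
        )
    pd.DataFrame(
        rows,
        columns=["clone_id", "position", "lesion_strand", "fate", "inserted_base", "ref", "alt"],
    ).to_csv(str(path), sep="\t", index=False)
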