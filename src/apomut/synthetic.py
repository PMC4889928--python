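"""Synthetic tumor-cohort generator.

Emulates the statistical structure the cohort analysis assumes in a
breast-cancer-like exome cohort: per-tumor gene expression (log-normal),
negative-binomially overdispersed per-class mutation counts whose means
rise with APOBEC3B expression (concentrated on TpC-context C classes) and
fall with PRIMPOL expression (strongest for C transversions), and a small
deficient subset (PRIMPOL expression ~0) with a doubled load.

The generated tables use the exact schemas the cohort analysis consumes,
so the analysis layer is fully testable without any external download.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .cohort import COLLAPSED_CLASSES, TumorMutation, reverse_complement_mutation
from .simulator import BASES

__all__ = ["CohortParams", "generate_cohort", "write_cohort"]

_DEFAULT_LAMBDA0 = {"C>A": 4.0, "C>G": 4.0, "C>T": 12.0, "T>A": 2.0, "T>C": 5.0, "T>G": 2.0}
# APOBEC effect concentrated on TpC-targetable C classes
_DEFAULT_ALPHA = {"C>A": 2.0, "C>G": 2.0, "C>T": 1.5, "T>A": 0.2, "T>C": 0.2, "T>G": 0.2}
# PRIMPOL protection strongest for C transversions (AP-site-derived)
_DEFAULT_PROTECTION = {"C>A": 0.5, "C>G": 0.5, "C>T": 0.3, "T>A": 0.2, "T>C": 0.2, "T>G": 0.2}
# probability a C-class mutation lies in a TpC dinucleotide
_DEFAULT_TPC_PROB = {"C>A": 0.54, "C>G": 0.54, "C>T": 0.54}

_DEFAULT_EXPRESSION = {
    # (log-normal location of log-expression, scale); RSEM-like magnitudes
    "APOBEC3B": (6.0, 1.0),
    "PRIMPOL": (5.5, 0.6),
    "POLH": (6.0, 0.5),
    "POLI": (5.8, 0.5),
    "POLK": (5.6, 0.5),
    "REV1": (6.2, 0.5),
    "CASP3": (7.0, 0.5),
    "CENPU": (5.0, 0.5),
}


@dataclass(frozen=True)
class CohortParams:
    """Parameters of the synthetic cohort.

    Per tumor the expected count of collapsed class ``c`` is::

        λ0[c] · (1 + α[c]·Ã3B) · (1 − s[c]·g(PRIMPOL)) · m

    where Ã3B is min-max-scaled APOBEC3B expression in [0, 1], g is the
    saturating map expr/(expr + cohort median) in [0, 1), and m is
    ``deficient_multiplier`` for deficient tumors (which additionally get
    PRIMPOL expression 0) and 1 otherwise. Counts are negative-binomial
    with dispersion ``overdispersion`` (smaller = more overdispersed).
    """

    n_tumors: int = 817
    deficient_fraction: float = 14 / 817
    expression_laws: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_EXPRESSION)
    )
    lambda0: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_LAMBDA0))
    apobec_effect: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_ALPHA))
    primpol_protection: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_PROTECTION)
    )
    tpc_prob: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_TPC_PROB))
    deficient_multiplier: float = 2.0
    indel_rates: tuple[float, float] = (1.0, 2.0)  # insertion, deletion means
    overdispersion: float = 3.0
    seed: int = 0

    def __post_init__(self):
        if self.n_tumors < 1:
            raise ValueError(f"n_tumors must be >= 1, got {self.n_tumors}")
        if not 0.0 <= self.deficient_fraction <= 1.0:
            raise ValueError("deficient_fraction must lie in [0, 1]")
        if self.deficient_multiplier < 1.0:
            raise ValueError("deficient_multiplier must be >= 1")
        if self.overdispersion <= 0:
            raise ValueError("overdispersion must be positive")
        for name in ("lambda0", "apobec_effect", "primpol_protection"):
            for cls, v in getattr(self, name).items():
                if cls not in COLLAPSED_CLASSES:
                    raise ValueError(f"{name}: unknown class {cls!r}")
                if v < 0:
                    raise ValueError(f"{name}[{cls}] must be >= 0, got {v}")
        for cls, v in self.tpc_prob.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"tpc_prob[{cls}] must lie in [0, 1]")
        for gene in ("APOBEC3B", "PRIMPOL"):
            if gene not in self.expression_laws:
                raise ValueError(f"expression_laws must include {gene}")


def _negative_binomial(rng, mean: np.ndarray, k: float) -> np.ndarray:
    """NB draws with mean ``mean`` and dispersion ``k`` (variance
    mean + mean²/k)."""
    mean = np.maximum(mean, 1e-12)
    return rng.negative_binomial(k, k / (k + mean))


def _sample_flanks(rng, cls: str, tpc: bool) -> tuple[str, str]:
    """Flanks on the pyrimidine strand for one mutation."""
    if cls.startswith("C"):
        flank5 = "T" if tpc else str(rng.choice(["A", "C", "G"]))
    else:
        flank5 = str(rng.choice(BASES))
    flank3 = str(rng.choice(BASES))
    return flank5, flank3


def generate_cohort(params: CohortParams):
    """Draw a cohort: roster, expression table, mutation records, truth.

    Returns
    -------
    (roster, expression, mutations, truth)
        ``roster`` is a DataFrame (tumor_id, deficient flag);
        ``expression`` a tumor × gene DataFrame; ``mutations`` a list of
        :class:`~apomut.cohort.TumorMutation` (each emitted on a random
        strand, so purine-reference records exercise the collapse);
        ``truth`` records the per-tumor per-class means and the params.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_tumors
    width = len(str(n - 1))
    tumor_ids = [f"TUMOR_{i:0{width}d}" for i in range(n)]

    deficient = rng.random(n) < params.deficient_fraction

    genes = list(params.expression_laws)
    expression = pd.DataFrame(index=pd.Index(tumor_ids, name="tumor_id"), columns=genes, dtype=float)
    for gene in genes:
        mu, sigma = params.expression_laws[gene]
        expression[gene] = rng.lognormal(mean=mu, sigma=sigma, size=n)
    expression.loc[deficient, "PRIMPOL"] = 0.0

    # min-max scale log-expression: the raw log-normal scale is dominated
    # by its right tail, which would concentrate the whole effect in a few
    # extreme tumors instead of a cohort-wide monotone trend
    a3b = np.log1p(expression["APOBEC3B"].to_numpy())
    a3b_scaled = (a3b - a3b.min()) / np.ptp(a3b) if np.ptp(a3b) else np.zeros(n)
    pp = expression["PRIMPOL"].to_numpy()
    pp_ref = float(np.median(pp[pp > 0])) if np.any(pp > 0) else 1.0
    g_pp = pp / (pp + pp_ref)

    multiplier = np.where(deficient, params.deficient_multiplier, 1.0)
    means: dict[str, np.ndarray] = {}
    counts: dict[str, np.ndarray] = {}
    for cls in COLLAPSED_CLASSES:
        lam0 = params.lambda0.get(cls, 0.0)
        alpha = params.apobec_effect.get(cls, 0.0)
        s = params.primpol_protection.get(cls, 0.0)
        mean = lam0 * (1.0 + alpha * a3b_scaled) * (1.0 - s * g_pp) * multiplier
        means[cls] = mean
        counts[cls] = _negative_binomial(rng, mean, params.overdispersion)

    ins_mean, del_mean = params.indel_rates
    insertions = _negative_binomial(rng, np.full(n, ins_mean) * multiplier, params.overdispersion)
    deletions = _negative_binomial(rng, np.full(n, del_mean) * multiplier, params.overdispersion)

    mutations: list[TumorMutation] = []
    for i, tumor in enumerate(tumor_ids):
        for cls in COLLAPSED_CLASSES:
            ref, alt = cls.split(">")
            p_tpc = params.tpc_prob.get(cls, 0.0)
            for _ in range(int(counts[cls][i])):
                tpc = bool(rng.random() < p_tpc) if ref == "C" else False
                flank5, flank3 = _sample_flanks(rng, cls, tpc)
                mut = TumorMutation(tumor, ref, alt, flank5, flank3)
                if rng.random() < 0.5:  # report on the purine strand
                    mut = reverse_complement_mutation(mut)
                mutations.append(mut)

    roster = pd.DataFrame(
        {
            "tumor_id": tumor_ids,
            "deficient": deficient.astype(int),
            "insertions": insertions,
            "deletions": deletions,
        }
    )
    truth = {
        "params": {
            "n_tumors": n,
            "deficient_fraction": params.deficient_fraction,
            "deficient_multiplier": params.deficient_multiplier,
            "overdispersion": params.overdispersion,
            "seed": params.seed,
        },
        "n_deficient": int(deficient.sum()),
        "per_class_mean": {cls: means[cls].tolist() for cls in COLLAPSED_CLASSES},
        "insertions": insertions.tolist(),
        "deletions": deletions.tolist(),
    }
    return roster, expression, mutations, truth


def write_cohort(roster, expression, mutations, truth, out_dir) -> dict[str, str]:
    """Write the cohort as the TSV/JSON files the analysis layer reads.

    Returns the map of logical name → path written.
    """
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "roster": out / "roster.tsv",
        "expression": out / "expression.tsv",
        "mutations": out / "mutations.tsv",
        "truth": out / "truth.json",
    }
    roster.to_csv(paths["roster"], sep="\t", index=False)
    expression.to_csv(paths["expression"], sep="\t")
    pd.DataFrame(
        [
            {
                "tumor_id": m.tumor_id,
                "ref": m.ref_base,
                "alt": m.alt_base,
                "flank5": m.flank5,
                "flank3": m.flank3,
            }
            for m in mutations
        ],
        columns=["tumor_id", "ref", "alt", "flank5", "flank3"],
    ).to_csv(paths["mutations"], sep="\t", index=False)
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=1)
    return {k: str(v) for k, v in paths.items()}
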