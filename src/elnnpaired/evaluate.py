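"""Partition-agreement indices, DE/NE error rates, and a paired-t baseline.

The agreement indices are the classic pair-counting family.  Writing the
G genes as C(G, 2) unordered pairs and counting

    a — pairs co-clustered in both partitions,
    b — co-clustered in truth only,
    c — co-clustered in the estimate only,
    d — separated in both,

gives Rand = (a + d) / C(G, 2), Jaccard = a / (a + b + c) and
Fowlkes--Mallows = a / sqrt((a + b)(a + c)).  The two chance-corrected
variants share the form (Rand - E[Rand]) / (1 - E[Rand]) and differ only in
the null model for E[Rand]: Hubert--Arabie uses the hypergeometric
expectation given both margins, Morey--Agresti the multinomial one
(E[sum n_ij^2] = sum_i a_i^2 sum_j b_j^2 / G^2).

Error rates collapse the three clusters to DE (OE or UE) vs NE:
FPR = detected-DE among truly-NE, FNR = detected-NE among truly-DE,
FDR = truly-NE among detected-DE, FNDR = truly-DE among detected-NE; an
empty reference set yields rate 0.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .model import InputError, PairedDiffMatrix, logger

__all__ = [
    "pair_counts",
    "agreement_indices",
    "error_rates",
    "paired_t_baseline",
    "evaluate_labels",
]


def _as_labels(x) -> np.ndarray:
    arr = np.asarray(x)
    if arr.ndim != 1:
        raise InputError("labels must be one-dimensional")
    return arr


def _contingency(true_labels: np.ndarray, est_labels: np.ndarray) -> np.ndarray:
    t_codes, _ = pd.factorize(true_labels)
    e_codes, _ = pd.factorize(est_labels)
    table = np.zeros((t_codes.max() + 1, e_codes.max() + 1), dtype=np.int64)
    np.add.at(table, (t_codes, e_codes), 1)
    return table


def pair_counts(true_labels, est_labels) -> tuple[int, int, int, int]:
    """(a, b, c, d) pair-agreement counts over all C(G, 2) unordered pairs."""
    t = _as_labels(true_labels)
    e = _as_labels(est_labels)
    if t.shape != e.shape:
        raise InputError(f"label length mismatch: {t.shape} vs {e.shape}")
    G = t.size
    if G < 2:
        raise InputError("need at least 2 items to count pairs")
    table = _contingency(t, e)

    def comb2(x: np.ndarray) -> int:
        x = x.astype(np.int64)
        return int((x * (x - 1) // 2).sum())

    a = comb2(table)
    b = comb2(table.sum(axis=1)) - a
    c = comb2(table.sum(axis=0)) - a
    total = G * (G - 1) // 2
    d = total - a - b - c
    return a, b, c, d


def agreement_indices(true_labels, est_labels) -> dict[str, float]:
    """Rand, Hubert--Arabie (HA), Morey--Agresti (MA), Fowlkes--Mallows, Jaccard."""
    t = _as_labels(true_labels)
    e = _as_labels(est_labels)
    a, b, c, d = pair_counts(t, e)
    total = a + b + c + d
    rand = (a + d) / total

    identical = bool(np.all(
        pd.factorize(t)[0] == pd.factorize(e)[0]
    ))
    if b + c == 0 and identical:
        # perfect agreement, including the all-one-cluster edge case where
        # the chance-corrected denominators vanish
        return {"Rand": 1.0, "HA": 1.0, "MA": 1.0, "FM": 1.0, "Jaccard": 1.0}

    jaccard = a / (a + b + c) if (a + b + c) > 0 else 0.0
    fm = a / np.sqrt((a + b) * (a + c)) if (a + b) > 0 and (a + c) > 0 else 0.0

    # Hubert--Arabie: hypergeometric expectation of the co-clustered count
    exp_a = (a + b) * (a + c) / total
    max_a = 0.5 * ((a + b) + (a + c))
    if max_a == exp_a:
        raise InputError("HA undefined: degenerate margins with disagreement")
    ha = (a - exp_a) / (max_a - exp_a)

    # Morey--Agresti: multinomial expectation of sum n_ij^2
    table = _contingency(t, e)
    G = t.size
    sum_ai2 = float((table.sum(axis=1).astype(float) ** 2).sum())
    sum_bj2 = float((table.sum(axis=0).astype(float) ** 2).sum())
    exp_nij2 = sum_ai2 * sum_bj2 / G**2
    denom = G * (G - 1)
    exp_rand = 1.0 + (2.0 * exp_nij2 - (sum_ai2 + sum_bj2)) / denom
    if exp_rand == 1.0:
        raise InputError("MA undefined: expected Rand equals 1 with disagreement")
    ma = (rand - exp_rand) / (1.0 - exp_rand)

    return {"Rand": float(rand), "HA": float(ha), "MA": float(ma),
            "FM": float(fm), "Jaccard": float(jaccard)}


def error_rates(true_labels, est_labels) -> dict[str, float]:
    """FPR, FNR, FDR, FNDR on the DE-vs-NE dichotomy (DE = OE or UE)."""
    t = _as_labels(true_labels)
    e = _as_labels(est_labels)
    if t.shape != e.shape:
        raise InputError(f"label length mismatch: {t.shape} vs {e.shape}")
    true_de = t != "NE"
    est_de = e != "NE"

    def rate(num: int, den: int) -> float:
        return num / den if den > 0 else 0.0

    return {
        "FPR": rate(int((est_de & ~true_de).sum()), int((~true_de).sum())),
        "FNR": rate(int((~est_de & true_de).sum()), int(true_de.sum())),
        "FDR": rate(int((~true_de & est_de).sum()), int(est_de.sum())),
        "FNDR": rate(int((true_de & ~est_de).sum()), int((~est_de).sum())),
    }


def paired_t_baseline(d: PairedDiffMatrix, alpha: float = 0.05) -> np.ndarray:
    """Per-gene one-sample t test on the differences with BH adjustment.

    A stand-in frequentist comparator: OE/UE where the BH-adjusted p-value
    is below ``alpha`` (signed by the gene mean), NE otherwise.
    """
    values = d.values
    res = stats.ttest_1samp(values, popmean=0.0, axis=1)
    pvals = np.asarray(res.pvalue, dtype=float)
    zero_var = values.std(axis=1) == 0
    if np.any(zero_var | ~np.isfinite(pvals)):
        logger.warning("paired_t_baseline: %d zero-variance/invalid rows treated as p=1",
                       int((zero_var | ~np.isfinite(pvals)).sum()))
        pvals = np.where(zero_var | ~np.isfinite(pvals), 1.0, pvals)
    reject, _, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    means = values.mean(axis=1)
    labels = np.full(d.n_genes, "NE", dtype="<U2")
    labels[reject & (means > 0)] = "OE"
    labels[reject & (means < 0)] = "UE"
    return labels


def evaluate_labels(true_labels, est_labels) -> dict[str, float]:
    """All five agreement indices plus the four error rates in one dict."""
    out = agreement_indices(true_labels, est_labels)
    out.update(error_rates(true_labels, est_labels))
    return out


def run_scenario_replicates(scenario: str, n_reps: int, G: int = 1000, n: int = 30,
                            seed: int = 0, alpha: float = 0.05,
                            fit_config=None) -> pd.DataFrame:
    """Replicate one simulation scenario and score both classifiers.

    ``scenario``: 'G' (hierarchical-mixture generator) or 'S' (simple
    normals).  Returns a long DataFrame with one row per (replicate, method,
    metric); per-replicate seeds are spawned from ``seed`` so replicates are
    independent but reproducible.
    """
    from .em import FitConfig, fit
    from .simulate import simulate_elnn, simulate_simple

    if scenario not in ("G", "S"):
        raise InputError(f"scenario must be 'G' or 'S', got {scenario!r}")
    fit_config = fit_config or FitConfig()
    child_seeds = np.random.SeedSequence(seed).generate_state(n_reps) % (2**31)
    rows = []
    for rep, s in enumerate(child_seeds):
        s = int(s)
        if scenario == "G":
            d, truth = simulate_elnn(G, n, seed=s)
        else:
            d, truth = simulate_simple(G, n, seed=s)
        results = {
            "eLNNpaired": fit(d, FitConfig(**{**fit_config.__dict__, "seed": s})).labels,
            "paired-t-BH": paired_t_baseline(d, alpha=alpha),
        }
        for method, est in results.items():
            for metric, value in evaluate_labels(truth.labels, est).items():
                rows.append({"scenario": f"{scenario}{n}", "replicate": rep,
                             "method": method, "metric": metric, "value": value})
    return pd.DataFrame(rows)


def summarize_replicates(report: pd.DataFrame) -> pd.DataFrame:
    """Mean and sd per (scenario, method, metric) — the replicate-table layout."""
    return (
        report.groupby(["scenario", "method", "metric"], sort=False)["value"]
        .agg(["mean", "std"])
        .rename(columns={"std": "sd"})
        .reset_index()
    )
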