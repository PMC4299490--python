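"""From in vitro culture counts to ligand function and feedback networks.

Each tested ligand's effect on three output populations (HSC-enriched,
progenitor, mature) relative to the basal-cytokine control is summarised as
a signed one-tail p-value from a random-intercept mixed linear model (the
experiment identifier is the random effect).  The sign carries the direction
of the estimated effect; the magnitude is the one-tailed p.  Arrow patterns
over the three populations are looked up in a 17-row decision table to assign
one of six functional categories (quiescence, self-renewal, differentiation
or proliferation induction, proliferation inhibition, or neutral); patterns
outside the table are indeterminate.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

POPULATIONS = ("hsc_enriched", "progenitor", "mature")
COUNT_OF = {
    "hsc_enriched": "n_hsc_enriched",
    "progenitor": "n_progenitor",
    "mature": "n_mature",
}

NEUTRAL = "neutral"
QUIESCENCE = "quiescence_induction"
SELF_RENEWAL = "self_renewal_induction"
DIFFERENTIATION = "differentiation_induction"
PROLIFERATION = "proliferation_induction"
PROLIF_INHIBITION = "proliferation_inhibition"
INDETERMINATE = "indeterminate"

FUNCTIONAL_CATEGORIES = (
    NEUTRAL,
    QUIESCENCE,
    SELF_RENEWAL,
    DIFFERENTIATION,
    PROLIFERATION,
    PROLIF_INHIBITION,
)

#: decision table: arrow triple over (HSC-enriched, progenitor, mature);
#: +1 = significant increase, -1 = significant decrease, 0 = no change
DECISION_TABLE: dict[tuple[int, int, int], str] = {
    (0, 0, 0): NEUTRAL,
    (0, 0, -1): QUIESCENCE,
    (0, -1, 0): QUIESCENCE,
    (1, 0, 0): SELF_RENEWAL,
    (0, 1, 0): DIFFERENTIATION,
    (0, 0, 1): DIFFERENTIATION,
    (0, 1, 1): DIFFERENTIATION,
    (-1, -1, 1): DIFFERENTIATION,
    (1, 1, 0): PROLIFERATION,
    (1, 1, -1): PROLIFERATION,
    (1, 1, 1): PROLIFERATION,
    (1, 0, 1): PROLIFERATION,
    (1, -1, 1): PROLIFERATION,
    (-1, -1, -1): PROLIF_INHIBITION,
    (-1, -1, 0): PROLIF_INHIBITION,
    (-1, 0, -1): PROLIF_INHIBITION,
    (-1, 0, 0): PROLIF_INHIBITION,
}

#: canonical arrow pattern used when *generating* data of a given category
CATEGORY_EFFECT_DIRECTIONS: dict[str, tuple[int, int, int]] = {
    NEUTRAL: (0, 0, 0),
    QUIESCENCE: (0, 0, -1),
    SELF_RENEWAL: (1, 0, 0),
    DIFFERENTIATION: (0, 1, 0),
    PROLIFERATION: (1, 1, 1),
    PROLIF_INHIBITION: (-1, -1, -1),
}

#: confidence level <-> significance threshold of the nested ANOVA p-values
CONFIDENCE_ALPHAS = {"high": 0.01, "intermediate": 0.02, "low": 0.05}


@dataclass
class LigandEffectRecord:
    ligand: str
    dose: float
    signed_p: tuple[float, float, float]  # (HSC-enriched, progenitor, mature)
    category: str
    confidence_level: str


# -- signed one-tail p-values from the mixed model -----------------------

def _mixed_model_signed_p(y: np.ndarray, is_ligand: np.ndarray, groups: np.ndarray) -> float:
    """Signed one-tail p for the condition effect, random intercept per experiment.

    Wald t on the REML estimate with nlme-style denominator degrees of
    freedom (N - n_groups - 1).  Falls back to OLS when only one experiment
    is present or the mixed fit fails.
    """
    import statsmodels.api as sm

    n_groups = len(np.unique(groups))
    exog = np.column_stack([np.ones_like(y), is_ligand])
    coef = se = None
    if n_groups >= 2:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.MixedLM(y, exog, groups).fit(reml=True)
            coef, se = res.fe_params[1], res.bse_fe[1]
            dfree = len(y) - n_groups - 1
        except (np.linalg.LinAlgError, ValueError):
            coef = None
    if coef is None or not np.isfinite(se) or se == 0:
        logger.warning("mixed fit degraded to a fixed-effect comparison")
        res = sm.OLS(y, exog).fit()
        coef, se = res.params[1], res.bse[1]
        dfree = len(y) - 2
    t = coef / se
    p_two = 2.0 * stats.t.sf(abs(t), dfree)
    p_one = max(p_two / 2.0, np.finfo(float).tiny)
    return float(np.sign(coef) * p_one) if coef != 0 else float(p_one)


def signed_pvalues(
    counts: pd.DataFrame,
    ligand_condition: str,
    dose: float | None = None,
    control: str = "BC",
) -> tuple[float, float, float]:
    """Signed one-tail p-values of a ligand condition vs the basal control.

    Counts are log(count + 1)-transformed; one population model per output
    population.  Nominal p-values, no multiplicity correction.
    """
    keep = counts["condition"].isin([control, ligand_condition])
    if dose is not None:
        keep &= (counts["condition"] == control) | (counts["dose"] == dose)
    sub = counts[keep]
    if sub["condition"].nunique() < 2:
        raise ValueError(
            f"condition '{ligand_condition}' and control '{control}' not both present"
        )
    is_ligand = (sub["condition"] == ligand_condition).to_numpy(dtype=float)
    groups = sub["experiment"].to_numpy()
    out = []
    for pop in POPULATIONS:
        y = np.log(sub[COUNT_OF[pop]].to_numpy(dtype=float) + 1.0)
        out.append(_mixed_model_signed_p(y, is_ligand, groups))
    return tuple(out)


# -- Table-1 classifier --------------------------------------------------

def _arrow(p: float, alpha: float) -> int:
    if abs(p) <= alpha:
        return 1 if p > 0 else -1
    return 0


def classify_ligand(signed_p: tuple[float, float, float], alpha: float = 0.02) -> str:
    """Map a signed p-value triple to a functional category at threshold alpha."""
    if alpha not in CONFIDENCE_ALPHAS.values():
        logger.warning("non-standard significance threshold alpha=%g", alpha)
    arrows = tuple(_arrow(p, alpha) for p in signed_p)
    return DECISION_TABLE.get(arrows, INDETERMINATE)


def is_context_sensitive(signed_p: tuple[float, float, float]) -> bool:
    """True when the category flips across the three confidence thresholds."""
    cats = {
        classify_ligand(signed_p, a) for a in CONFIDENCE_ALPHAS.values()
    }
    return len(cats - {NEUTRAL}) > 1


def most_effective_dose(
    dose_pvalues: dict[float, tuple[float, float, float]], alpha: float = 0.02
) -> float:
    """The dose with the smallest |signed p| on any population (ties: lower dose).

    A ligand with no significant effect at any dose reports its highest dose.
    """
    if not dose_pvalues:
        raise ValueError("no doses supplied")
    best = {d: min(abs(p) for p in ps) for d, ps in dose_pvalues.items()}
    if min(best.values()) > alpha:
        return max(dose_pvalues)
    return min(sorted(best), key=lambda d: best[d])


def classify_records(
    counts: pd.DataFrame,
    ligands: list[str] | None = None,
    confidence_level: str = "intermediate",
    control: str = "BC",
) -> list[LigandEffectRecord]:
    """Fit, pick each ligand's most effective dose, and classify it."""
    alpha = CONFIDENCE_ALPHAS[confidence_level]
    if ligands is None:
        ligands = [c for c in counts["condition"].unique() if c != control]
    records = []
    for lig in ligands:
        doses = sorted(counts.loc[counts["condition"] == lig, "dose"].unique())
        dose_p = {d: signed_pvalues(counts, lig, dose=d, control=control) for d in doses}
        dose = most_effective_dose(dose_p, alpha)
        p = dose_p[dose]
        category = classify_ligand(p, alpha)
        if is_context_sensitive(p):
            category = INDETERMINATE
        records.append(LigandEffectRecord(lig, dose, p, category, confidence_level))
    return records


# -- prediction-capacity binomial test -----------------------------------

@dataclass
class BinomialCapacity:
    point: float
    tail: float
    expectation: float


def prediction_capacity_test(n_tested: int, n_effective: int, p0: float = 0.5) -> BinomialCapacity:
    """Binomial model of the ligand-selection process, X ~ B(n_tested, p0)."""
    if not 0 <= n_effective <= n_tested:
        raise ValueError("n_effective must lie in [0, n_tested]")
    if not 0.0 < p0 < 1.0:
        raise ValueError("p0 must lie in (0, 1)")
    dist = stats.binom(n_tested, p0)
    return BinomialCapacity(
        point=float(dist.pmf(n_effective)),
        tail=float(dist.sf(n_effective - 1)),
        expectation=n_tested * p0,
    )


# -- hypergeometric Z-score enrichment -----------------------------------

#: enrichment convention: scores above this are called enriched
HG_Z_THRESHOLD = 1.15


def hg_zscore(N: int, m: int, n: int, k: int) -> float:
    """Standardized hypergeometric over-representation score.

    ``N`` ligands in the universe, ``m`` in the function group, ``n`` drawn
    by the cell type, ``k`` in the overlap; Z = (k - nm/N) / sd under the
    hypergeometric null.
    """
    if N <= 1 or n == 0 or m == 0:
        raise ValueError("hypergeometric Z undefined for N<=1 or empty margins")
    mean = n * m / N
    var = n * (m / N) * (1 - m / N) * (N - n) / (N - 1)
    if var == 0:
        return 0.0 if k == mean else float(np.sign(k - mean) * np.inf)
    return float((k - mean) / np.sqrt(var))


def celltype_functional_enrichment(
    net,
    records: list[LigandEffectRecord],
    target_cell: str = "HSCe",
) -> pd.DataFrame:
    """Per cell type, HG Z-scores of its produced ligands over the categories.

    The universe is the set of categorized ligands that bind the target cell
    in the network (indeterminate ligands are excluded).  Cell types
    producing none of the universe ligands are skipped with a warning.
    """
    categorized = {
        r.ligand: r.category for r in records if r.category != INDETERMINATE
    }
    binders = set(net.binding.index[net.binding[target_cell] >= 1])
    universe = sorted(set(categorized) & binders)
    N = len(universe)
    if N == 0:
        raise ValueError("no categorized target-binding ligands in the network")
    cat_of = {lig: categorized[lig] for lig in universe}
    cats = sorted({c for c in cat_of.values()})

    rows = {}
    for cell in net.production.index:
        produced = [
            lig for lig in universe if net.production.loc[cell, lig] >= 1
        ]
        n = len(produced)
        if n == 0:
            logger.warning("cell %s produces no categorized ligands; skipped", cell)
            continue
        row = {}
        for cat in cats:
            m = sum(1 for c in cat_of.values() if c == cat)
            k = sum(1 for lig in produced if cat_of[lig] == cat)
            row[cat] = hg_zscore(N, m, n, k)
        rows[cell] = row
    return pd.DataFrame.from_dict(rows, orient="index")[cats]


# -- weighted feedback networks ------------------------------------------

FEEDBACK_MODES = ("receptor", "frequency", "compartment")


def build_feedback_network(
    net,
    records: list[LigandEffectRecord],
    lr,
    target_receptor_levels: dict[str, float] | pd.Series,
    mode: str = "receptor",
    freqs: pd.Series | None = None,
    compartment_weights: dict[str, float] | None = None,
    others_label: str = "Others",
) -> pd.DataFrame:
    """Signal strength per (producing cell, functional category) toward the target.

    ``receptor`` mode sums, over the cell's categorized ligands and their
    cognate receptors expressed by the target cell, the receptor expression
    level.  ``frequency`` mode multiplies by the producing cell's frequency
    (the "Others" pseudo-cell is dropped: it has no frequency).
    ``compartment`` mode additionally multiplies by a per-cell reach factor
    (peripheral cells typically 0.1).
    """
    if mode not in FEEDBACK_MODES:
        raise ValueError(f"unknown mode '{mode}'")
    levels = pd.Series(target_receptor_levels, dtype=float)
    categorized = {r.ligand: r.category for r in records if r.category != INDETERMINATE}

    cells = list(net.production.index)
    if mode in ("frequency", "compartment"):
        cells = [c for c in cells if c != others_label]
        if freqs is None:
            raise ValueError(f"mode '{mode}' requires cell frequencies")
        missing = [c for c in cells if c not in freqs.index]
        if missing:
            raise ValueError(f"missing frequencies for cells: {missing}")

    rows = []
    for cell in cells:
        for lig, cat in categorized.items():
            if lig not in net.production.columns or net.production.loc[cell, lig] < 1:
                continue
            receptors = lr.cognate_receptors(lig) & set(levels.index)
            weight = float(levels[sorted(receptors)].sum())
            if weight == 0:
                continue
            if mode in ("frequency", "compartment"):
                weight *= float(freqs[cell])
            if mode == "compartment":
                weight *= float((compartment_weights or {}).get(cell, 1.0))
            rows.append({"cell": cell, "category": cat, "ligand": lig, "weight": weight})
    edges = pd.DataFrame(rows, columns=["cell", "category", "ligand", "weight"])
    if edges.empty:
        return pd.DataFrame(columns=["cell", "category", "weight"])
    out = edges.groupby(["cell", "category"], as_index=False)["weight"].sum()
    out["mode"] = mode
    return out


def feedback_network_graph(edges: pd.DataFrame, target: str = "HSC-e"):
    """Directed cell -> category -> target graph from a feedback edge table."""
    import networkx as nx

    g = nx.DiGraph()
    for _, row in edges.iterrows():
        g.add_node(row["cell"], kind="cell")
        g.add_node(row["category"], kind="category")
        g.add_edge(row["cell"], row["category"], weight=float(row["weight"]))
        g.add_edge(row["category"], target, weight=1.0)
    if target in g:
        g.nodes[target]["kind"] = "target"
    return g


# -- generic permutation test for category-factor association -------------

def permutation_category_test(
    ligand_categories: dict[str, str],
    factor_ligands: set[str],
    category: str,
    n_perm: int = 10_000,
    seed: int = 0,
) -> float:
    """How often random recategorizations link a factor to a category this often.

    Shuffles category labels over ligands and counts permutations in which at
    least as many factor-linked ligands fall in ``category`` as observed.
    """
    rng = np.random.default_rng(seed)
    ligs = sorted(ligand_categories)
    labels = np.array([ligand_categories[l] for l in ligs])
    in_factor = np.array([l in factor_ligands for l in ligs])
    observed = int(((labels == category) & in_factor).sum())
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        if ((perm == category) & in_factor).sum() >= observed:
            hits += 1
    return hits / n_perm
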