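"""GWAS-based module scoring: the challenge's empirical assessment.

Gene-level GWAS association p-values over a network's gene background are
rank-transformed to uniform, mapped through the chi-square(1) upper-quantile
function (so the most significant genes receive the largest scores), summed
over a module of size m and tested against a chi-square(m) distribution.
Because of the initial rank transform this is a *competitive* enrichment
test: it asks whether module genes score better than the other genes of the
same network, and is invariant to any rank-preserving transformation of the
input p-values.

A module is *trait-associated* if its Benjamini-Hochberg q-value is below
the FDR cutoff for at least one GWAS; the challenge score of a submission is
the number of its trait-associated modules, each counted once no matter how
many traits it hits, summed over networks. Ranking robustness is assessed
by subsampling the GWAS collection and comparing methods to the best one
with a paired Bayes factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class GeneScoreTable:
    """Per-GWAS gene -> p-value mapping over a declared background."""

    gwas_id: str
    scores: dict[str, float]
    background: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        for g, p in self.scores.items():
            if not (0 < p <= 1):
                raise ValueError(f"gene {g!r}: p-value {p} outside (0, 1]")
        if not self.background:
            self.background = set(self.scores)


def chi2_transform(
    table: GeneScoreTable, missing: str = "one"
) -> dict[str, float]:
    """Rank-transform gene p-values and map to chi-square(1) scores.

    Ranks are ascending in p with average ranks for ties; the uniformized
    value is ``u = (rank - 0.5) / N`` and the score is the chi-square(1)
    upper quantile at u, so the smallest p-value gets the largest score.
    Background genes without a recorded score receive p = 1 before ranking
    (``missing="one"``) or are excluded (``missing="drop"``).
    """
    if missing not in ("one", "drop"):
        raise ValueError("missing policy must be 'one' or 'drop'")
    genes = sorted(table.background)
    if missing == "drop":
        genes = [g for g in genes if g in table.scores]
    if not genes:
        raise ValueError("no scored genes in background")
    p = np.array([table.scores.get(g, 1.0) for g in genes])
    ranks = stats.rankdata(p, method="average")
    u = (ranks - 0.5) / len(genes)
    s = stats.chi2.isf(u, df=1)
    return dict(zip(genes, s))


def module_pvalue(chi2_scores: dict[str, float], module) -> tuple[float, float]:
    """Competitive module enrichment: sum of chi-square(1) gene scores tested
    against chi-square(m). Returns ``(T, nominal_p)``."""
    module = set(module)
    if not module:
        raise ValueError("empty module")
    missing = module - set(chi2_scores)
    if missing:
        raise ValueError(
            f"module genes outside the scored background: {sorted(missing)[:5]}"
        )
    t = float(sum(chi2_scores[g] for g in module))
    return t, float(stats.chi2.sf(t, df=len(module)))


def score_modules(modules, table: GeneScoreTable, missing: str = "one") -> pd.DataFrame:
    """Score every module of a ModuleSet against one GWAS.

    Returns a frame with columns module_id, gwas_id, T, pvalue.
    """
    scores = chi2_transform(table, missing=missing)
    rows = []
    for i, module in enumerate(modules.modules):
        t, p = module_pvalue(scores, module)
        rows.append((i, table.gwas_id, t, p))
    return pd.DataFrame(rows, columns=["module_id", "gwas_id", "T", "pvalue"])


@dataclass
class ScoreReport:
    per_network: dict[str, int]
    overall: int
    fdr_cutoff: float
    table: pd.DataFrame  # network, module_id, gwas_id, T, pvalue, qvalue, significant

    def trait_modules(self, network: str) -> set[int]:
        t = self.table
        sel = t[(t["network"] == network) & t["significant"]]
        return set(sel["module_id"])


def challenge_score(
    predictions: dict[str, "ModuleSet"],
    gwas_tables: dict[str, list[GeneScoreTable]],
    fdr: float = 0.05,
    missing: str = "one",
) -> ScoreReport:
    """Count trait-associated modules across networks at an FDR cutoff.

    ``predictions`` maps network id -> ModuleSet; ``gwas_tables`` maps
    network id -> the GWAS gene-score tables evaluated on that network (the
    background of each table must cover the module genes). BH correction is
    applied per (network, GWAS) over that submission's module p-values; a
    module significant for several traits still counts once.
    """
    frames = []
    for net_id, ms in predictions.items():
        for table in gwas_tables[net_id]:
            df = score_modules(ms, table, missing=missing)
            df.insert(0, "network", net_id)
            if len(df):
                _, q, _, _ = multipletests(df["pvalue"], method="fdr_bh")
                df["qvalue"] = np.maximum(q, df["pvalue"])
                df["significant"] = df["qvalue"] < fdr
            else:
                df["qvalue"] = []
                df["significant"] = []
            frames.append(df)
    table = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(
            columns=["network", "module_id", "gwas_id", "T", "pvalue", "qvalue", "significant"]
        )
    )
    per_network = {}
    for net_id in predictions:
        sel = table[(table["network"] == net_id) & table["significant"]]
        per_network[net_id] = int(sel["module_id"].nunique())
    return ScoreReport(
        per_network=per_network,
        overall=int(sum(per_network.values())),
        fdr_cutoff=fdr,
        table=table,
    )


@dataclass
class RobustnessReport:
    scores: pd.DataFrame  # method x subsample scores
    ranks: pd.DataFrame
    bayes_factors: dict[str, float]
    reference: str
    ties: set[str]


def subsample_robustness(
    hits: pd.DataFrame,
    n_subsample: int,
    n_draws: int = 1000,
    seed: int = 0,
    tie_threshold: float = 3.0,
) -> RobustnessReport:
    """Ranking robustness under GWAS subsampling.

    ``hits`` has columns method, gwas_id, module_id listing, per method, the
    (module, GWAS) pairs called significant in the full evaluation (for
    multi-network submissions use globally unique module ids). Significance
    calls are fixed from the full run; each of ``n_draws`` subsamples keeps
    ``n_subsample`` GWASs drawn without replacement and re-evaluates only the
    "associated with >= 1 retained GWAS" union per method. The reference is
    the method with the best full score; the paired Bayes factor of method m
    is  #(reference beats m) / #(m beats or ties reference),  and methods
    with K below ``tie_threshold`` (3 by convention) tie with the reference.
    """
    required = {"method", "gwas_id", "module_id"}
    if not required <= set(hits.columns):
        raise ValueError(f"hits table needs columns {sorted(required)}")
    gwas_ids = sorted(hits["gwas_id"].unique())
    if n_subsample > len(gwas_ids):
        raise ValueError(
            f"cannot draw {n_subsample} GWASs from a set of {len(gwas_ids)}"
        )
    methods = sorted(hits["method"].unique())
    full_scores = {
        m: hits.loc[hits["method"] == m, "module_id"].nunique() for m in methods
    }
    reference = max(methods, key=lambda m: (full_scores[m], m))
    rng = np.random.default_rng(seed)
    per_method = {
        m: hits[hits["method"] == m][["gwas_id", "module_id"]] for m in methods
    }
    score_rows = []
    for _ in range(n_draws):
        keep = set(rng.choice(gwas_ids, size=n_subsample, replace=False))
        row = {}
        for m in methods:
            sub = per_method[m]
            row[m] = sub.loc[sub["gwas_id"].isin(keep), "module_id"].nunique()
        score_rows.append(row)
    scores = pd.DataFrame(score_rows)
    ranks = scores.rank(axis=1, ascending=False, method="min")
    bayes = {}
    for m in methods:
        if m == reference:
            continue
        ref_wins = int((scores[reference] > scores[m]).sum())
        m_wins_or_ties = int((scores[m] >= scores[reference]).sum())
        bayes[m] = ref_wins / m_wins_or_ties if m_wins_or_ties else float("inf")
    ties = {m for m, k in bayes.items() if k < tie_threshold}
    return RobustnessReport(
        scores=scores,
        ranks=ranks,
        bayes_factors=bayes,
        reference=reference,
        ties=ties,
    )
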