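"""Covariate-adjusted metabolite-outcome associations and their concordance
between real and imputed datasets (Bland-Altman agreement on paired betas)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "AssociationRecord",
    "ConcordanceReport",
    "fit_association",
    "run_association_panel",
    "concordance",
    "match_external_panel",
]


@dataclass
class AssociationRecord:
    metabolite: str
    outcome: str
    beta: float
    se: float
    pvalue: float
    n: int
    dataset: str = "real"

    def __post_init__(self):
        if not np.isfinite(self.beta):
            raise ValueError("non-finite beta")
        if not self.se > 0:
            raise ValueError("standard error must be positive")


@dataclass
class ConcordanceReport:
    outcome: str
    pairs: pd.DataFrame  # index metabolite; beta_real, beta_imputed, diff, flagged
    spearman_rho: float
    mean_difference: float
    sd_difference: float
    limits: tuple[float, float]  # mean +- 1.96 SD
    unmatched: list[str]

    @property
    def n_flagged(self) -> int:
        return int(self.pairs["flagged"].sum())

    @property
    def pct_flagged(self) -> float:
        return 100.0 * self.n_flagged / len(self.pairs)


def _standardise(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=0)
    if sd == 0.0:
        raise ValueError("cannot standardise a constant variable")
    return (x - x.mean()) / sd


def fit_association(
    metabolite: np.ndarray,
    outcome: np.ndarray,
    age: np.ndarray,
    sex: np.ndarray,
    metabolite_id: str = "",
    outcome_name: str = "",
    dataset: str = "real",
) -> AssociationRecord:
    """OLS of standardised outcome on standardised metabolite, adjusted for
    age (standardised) and sex (0/1, not standardised); complete cases only."""
    data = np.column_stack([metabolite, outcome, age, sex]).astype(float)
    complete = ~np.isnan(data).any(axis=1)
    data = data[complete]
    n = data.shape[0]
    if n < 10:
        raise ValueError(f"need at least 10 complete cases, got {n}")
    met, out, age_c, sex_c = data.T
    design = sm.add_constant(
        np.column_stack([_standardise(met), _standardise(age_c), sex_c])
    )
    fit = sm.OLS(_standardise(out), design).fit()
    return AssociationRecord(
        metabolite=metabolite_id,
        outcome=outcome_name,
        beta=float(fit.params[1]),
        se=float(fit.bse[1]),
        pvalue=float(fit.pvalues[1]),
        n=n,
        dataset=dataset,
    )


def run_association_panel(
    matrix: pd.DataFrame,
    phenotypes: pd.DataFrame,
    metabolites: list[str],
    outcomes: list[str],
    dataset: str = "real",
    log_transform: tuple[str, ...] = (),
) -> list[AssociationRecord]:
    """One record per metabolite per outcome. ``matrix`` is samples x
    metabolites with the phenotype table aligned on sample id."""
    if not metabolites:
        raise ValueError("empty metabolite set")
    missing = [m for m in metabolites if m not in matrix.columns]
    if missing:
        raise ValueError(f"metabolites absent from matrix: {missing[:5]}")
    pheno = phenotypes.loc[matrix.index]
    records = []
    for outcome in outcomes:
        y = pheno[outcome].to_numpy(dtype=float)
        if outcome in log_transform:
            y = np.log(y)
        for metabolite in metabolites:
            records.append(
                fit_association(
                    matrix[metabolite].to_numpy(dtype=float),
                    y,
                    pheno["age"].to_numpy(dtype=float),
                    pheno["sex"].to_numpy(dtype=float),
                    metabolite_id=metabolite,
                    outcome_name=outcome,
                    dataset=dataset,
                )
            )
    return records


def records_frame(records: list[AssociationRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


def concordance(
    real: list[AssociationRecord],
    imputed: list[AssociationRecord],
    outcome: str,
) -> ConcordanceReport:
    """Pair betas by metabolite and assess agreement.

    Differences are real minus imputed; metabolites whose difference
    deviates from the mean difference by more than 1.96 SD are flagged
    (Bland-Altman convention)."""
    real_b = {r.metabolite: r.beta for r in real if r.outcome == outcome}
    imp_b = {r.metabolite: r.beta for r in imputed if r.outcome == outcome}
    shared = sorted(set(real_b) & set(imp_b))
    unmatched = sorted(set(real_b) ^ set(imp_b))
    if len(shared) < 3:
        raise ValueError(f"need >= 3 paired metabolites for outcome {outcome!r}")
    pairs = pd.DataFrame(
        {
            "beta_real": [real_b[m] for m in shared],
            "beta_imputed": [imp_b[m] for m in shared],
        },
        index=pd.Index(shared, name="metabolite"),
    )
    pairs["diff"] = pairs["beta_real"] - pairs["beta_imputed"]
    mean_d = float(pairs["diff"].mean())
    sd_d = float(pairs["diff"].std(ddof=1))
    pairs["flagged"] = (pairs["diff"] - mean_d).abs() > 1.96 * sd_d
    rho = float(stats.spearmanr(pairs["beta_real"], pairs["beta_imputed"]).statistic)
    return ConcordanceReport(
        outcome=outcome,
        pairs=pairs,
        spearman_rho=rho,
        mean_difference=mean_d,
        sd_difference=sd_d,
        limits=(mean_d - 1.96 * sd_d, mean_d + 1.96 * sd_d),
        unmatched=unmatched,
    )


def plot_concordance(report: ConcordanceReport, path) -> None:
    """Scatter of paired betas plus the Bland-Altman panel, written to file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
    pairs = report.pairs
    ax1.scatter(pairs["beta_real"], pairs["beta_imputed"], s=12, alpha=0.7)
    lim = max(pairs[["beta_real", "beta_imputed"]].abs().max()) * 1.1
    ax1.plot([-lim, lim], [-lim, lim], "k--", lw=0.8)
    ax1.set_xlabel("real beta")
    ax1.set_ylabel("imputed beta")
    ax1.set_title(f"{report.outcome}: rho = {report.spearman_rho:.2f}")
    means = (pairs["beta_real"] + pairs["beta_imputed"]) / 2
    colors = np.where(pairs["flagged"], "crimson", "steelblue")
    ax2.scatter(means, pairs["diff"], s=12, c=colors, alpha=0.7)
    ax2.axhline(report.mean_difference, color="k", lw=0.8)
    for limit in report.limits:
        ax2.axhline(limit, color="k", ls="--", lw=0.8)
    ax2.set_xlabel("mean beta")
    ax2.set_ylabel("real - imputed")
    ax2.set_title(f"{report.n_flagged} flagged ({report.pct_flagged:.1f}%)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def match_external_panel(
    imputed: list[AssociationRecord],
    external: list[AssociationRecord],
    name_map: dict[str, str],
    outcome: str,
    case_insensitive: bool = False,
) -> ConcordanceReport:
    """Concordance restricted to metabolites mapped onto an external panel.

    ``name_map`` maps imputed metabolite ids to external ids (exact string
    match by default)."""
    if not name_map:
        raise ValueError("empty name map")

    def norm(s: str) -> str:
        return s.lower() if case_insensitive else s

    ext_by_name = {norm(r.metabolite): r for r in external if r.outcome == outcome}
    mapped: list[AssociationRecord] = []
    for rec in imputed:
        if rec.outcome != outcome or rec.metabolite not in name_map:
            continue
        ext = ext_by_name.get(norm(name_map[rec.metabolite]))
        if ext is None:
            continue
        mapped.append(
            AssociationRecord(
                metabolite=rec.metabolite,
                outcome=outcome,
                beta=ext.beta,
                se=ext.se,
                pvalue=ext.pvalue,
                n=ext.n,
                dataset="matched-external",
            )
        )
    if not mapped:
        raise ValueError("no metabolites could be matched to the external panel")
    kept = {r.metabolite for r in mapped}
    imputed_kept = [r for r in imputed if r.outcome == outcome and r.metabolite in kept]
    return concordance(mapped, imputed_kept, outcome)
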