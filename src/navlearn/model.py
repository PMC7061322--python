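"""Cohort-level model: end-to-end navigational-learning analysis.

``NavigationalLearningModel`` bundles a cohort's latency series and
metrics table; ``fit`` runs the full pipeline —

    derive learning rates -> permutation screen -> per-metric MAD screen
    -> directional Pearson/Spearman with default Bayes factors and credible
    intervals -> fornix-vs-ILF comparisons (Steiger Z + bootstrap)
    -> partial correlations (hippocampal proportional volume; gender)
    -> Bonferroni-corrected alpha

— and returns a ``NavigationalLearningResults`` carrying every table plus a
JSON-serialisable report.  The whole run is reproducible from the master
seed: stage and per-participant RNG substreams are spawned from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import io as nio
from .cohort import CohortParams, SimulatedCohort, simulate_cohort
from .learning import LatencySeries, derive_learning_rate
from .screening import flag_nonlearners, mad_outlier_filter
from .stats import (
    bonferroni_alpha,
    bootstrap_compare_dependent_correlations,
    partial_correlation,
    pearson_directional,
    spearman_directional,
    steiger_z_dependent,
)

__all__ = [
    "AnalysisConfig",
    "NavigationalLearningModel",
    "NavigationalLearningResults",
    "run_full_analysis",
]

SCHEMA_VERSION = 1

#: Analysis metrics with the predicted direction of their association with
#: the learning-rate index b (and with mean latency): higher MD ~ slower
#: learning (positive), higher FA ~ faster learning (negative).
METRIC_DIRECTIONS = {
    "fornix_md": "greater",
    "fornix_fa": "less",
    "ilf_md": "greater",
    "ilf_fa": "less",
}

MEASURES = ("b", "mean_latency_to_cutoff")


@dataclass(frozen=True)
class AnalysisConfig:
    """Pipeline settings; the defaults reproduce the reference analysis
    settings (500 permutations, central 68% null interval, 2.5 MAD,
    alpha .05 over 2 comparisons per metric) without user input."""

    latency_path: str | None = None
    metrics_path: str | None = None
    simulate: CohortParams | None = None
    fit_method: str = "loglog_ols"
    n_perm: int = 500
    ci_level: float = 0.68
    threshold_rule: str = "percentile"
    pipeline_mode: str = "full"
    mad_threshold: float = 2.5
    alpha: float = 0.05
    comparisons_per_metric: int = 2
    n_boot: int = 1000
    include_excluded_in_mean_latency: bool = False
    seed: int | None = None

    def settings_dict(self) -> dict:
        d = {
            k: v
            for k, v in asdict(self).items()
            if k not in ("latency_path", "metrics_path", "simulate")
        }
        d["corrected_alpha"] = bonferroni_alpha(self.alpha, self.comparisons_per_metric)
        if self.simulate is not None:
            d["simulate"] = asdict(self.simulate)
        return d


def _py(v):
    """Coerce numpy scalars for JSON serialisation."""
    if isinstance(v, (np.floating,)):
        return float(v)
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.bool_,)):
        return bool(v)
    return v


def _records(df: pd.DataFrame) -> list[dict]:
    return [{k: _py(v) for k, v in rec.items()} for rec in df.to_dict("records")]


class NavigationalLearningModel:
    """Navigational-learning analysis for one cohort.

    Parameters
    ----------
    series : list of LatencySeries
        Per-participant trial latencies.
    metrics : DataFrame
        Per-participant tract metrics and covariates (see
        :func:`navlearn.io.read_metrics_table` for the schema).
    config : AnalysisConfig
    ground_truth : DataFrame, optional
        Generator truth for synthetic cohorts; carried through to the
        cohort table so recovery can be scored.
    """

    def __init__(
        self,
        series: list[LatencySeries],
        metrics: pd.DataFrame,
        config: AnalysisConfig | None = None,
        ground_truth: pd.DataFrame | None = None,
    ):
        if not series:
            raise ValueError("cohort must contain at least one participant")
        ids = [s.participant_id for s in series]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate participant ids")
        missing = set(ids) - set(metrics["participant_id"].astype(str))
        if missing:
            raise ValueError(f"metrics table lacks participants {sorted(missing)}")
        self.series = list(series)
        self.metrics = metrics.copy()
        self.metrics["participant_id"] = self.metrics["participant_id"].astype(str)
        self.config = config or AnalysisConfig()
        self.ground_truth = ground_truth

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_csv(
        cls, latency_path, metrics_path, config: AnalysisConfig | None = None
    ) -> "NavigationalLearningModel":
        series = nio.read_latency_table(latency_path)
        metrics = nio.read_metrics_table(metrics_path)
        return cls(series, metrics, config)

    @classmethod
    def from_simulation(
        cls, params: CohortParams, config: AnalysisConfig | None = None
    ) -> "NavigationalLearningModel":
        sim = simulate_cohort(params)
        return cls.from_simulated(sim, config)

    @classmethod
    def from_simulated(
        cls, sim: SimulatedCohort, config: AnalysisConfig | None = None
    ) -> "NavigationalLearningModel":
        series = [
            LatencySeries(
                str(row[0]), np.asarray(row[1:], dtype=float), sim.params.t_max
            )
            for row in sim.latencies.itertuples(index=False)
        ]
        return cls(series, sim.metrics, config, ground_truth=sim.ground_truth)

    # -- pipeline ----------------------------------------------------------

    def fit(self, seed: int | None = None) -> "NavigationalLearningResults":
        """Run the full pipeline; ``seed`` overrides the config seed."""
        cfg = self.config
        master = cfg.seed if seed is None else seed
        screen_ss, boot_ss = np.random.SeedSequence(master).spawn(2)

        try:
            learning = self._learning_table()
        except ValueError as e:
            raise RuntimeError(f"[learning] {e}") from e
        try:
            exclusions, _ = flag_nonlearners(
                self.series,
                n_perm=cfg.n_perm,
                seed=screen_ss,
                pipeline_mode=cfg.pipeline_mode,
                threshold_rule=cfg.threshold_rule,
                ci_level=cfg.ci_level,
            )
        except ValueError as e:
            raise RuntimeError(f"[screening] {e}") from e

        cohort = learning.merge(exclusions, on="participant_id")
        cohort = cohort.merge(self.metrics, on="participant_id")
        cohort["proportional_hc_volume"] = nio.proportional_volume(
            cohort["hippocampal_volume"].to_numpy(), cohort["etiv"].to_numpy()
        )
        if self.ground_truth is not None:
            cohort = cohort.merge(self.ground_truth, on="participant_id", how="left")

        try:
            correlations, keep_masks = self._correlations(cohort)
            comparisons = self._comparisons(cohort, keep_masks, boot_ss)
            partials = self._partials(cohort, keep_masks)
        except ValueError as e:
            raise RuntimeError(f"[inference] {e}") from e

        report = {
            "schema_version": SCHEMA_VERSION,
            "seed": master,
            "settings": cfg.settings_dict(),
            "exclusions": _records(exclusions),
            "learning": _records(learning),
            "correlations": correlations,
            "comparisons": comparisons,
            "partial_correlations": partials,
            "alpha": {
                "alpha": cfg.alpha,
                "comparisons_per_metric": cfg.comparisons_per_metric,
                "corrected_alpha": bonferroni_alpha(
                    cfg.alpha, cfg.comparisons_per_metric
                ),
            },
        }
        return NavigationalLearningResults(self, cohort, report)

    def _learning_table(self) -> pd.DataFrame:
        rows = []
        for s in self.series:
            res = derive_learning_rate(s, method=self.config.fit_method)
            rows.append(
                {
                    "participant_id": s.participant_id,
                    "a": res.power.a,
                    "b": res.power.b,
                    "r_squared": res.power.r_squared,
                    "cutoff_trial": res.quadratic.cutoff_trial,
                    "used_all_trials": res.quadratic.used_all_trials,
                    "mean_latency_to_cutoff": res.mean_latency_to_cutoff,
                }
            )
        return pd.DataFrame(rows)

    def _measure_base(self, cohort: pd.DataFrame, measure: str) -> pd.DataFrame:
        if measure == "b" or not self.config.include_excluded_in_mean_latency:
            return cohort[~cohort["excluded"]]
        return cohort

    def _correlations(self, cohort: pd.DataFrame):
        """Directional Pearson/Spearman per (measure, metric) pair.

        The MAD screen runs per metric within each measure's base set; the
        reported n for a pair is always (behaviourally retained) minus
        (MAD-removed for that metric).
        """
        cfg = self.config
        out = []
        keep_masks: dict[tuple[str, str], pd.Series] = {}
        for measure in MEASURES:
            base = self._measure_base(cohort, measure)
            for metric, alternative in METRIC_DIRECTIONS.items():
                mask = mad_outlier_filter(
                    base[metric].to_numpy(), threshold=cfg.mad_threshold
                ).keep
                keep = pd.Series(mask, index=base.index)
                keep_masks[(measure, metric)] = keep
                sub = base[keep.to_numpy()]
                pe = pearson_directional(
                    sub[metric].to_numpy(), sub[measure].to_numpy(), alternative
                )
                sp = spearman_directional(
                    sub[metric].to_numpy(), sub[measure].to_numpy(), alternative
                )
                out.append(
                    {
                        "measure": measure,
                        "metric": metric,
                        "alternative": alternative,
                        "n": int(len(sub)),
                        "mad_removed": [
                            str(p) for p in base.loc[~keep, "participant_id"]
                        ],
                        "pearson": {
                            "r": pe.estimate, "p": pe.p, "bf": pe.bf,
                            "bci": [pe.bci_low, pe.bci_high],
                        },
                        "spearman": {
                            "rho": sp.estimate, "p": sp.p, "bf": sp.bf,
                            "bci": [sp.bci_low, sp.bci_high],
                        },
                    }
                )
        return out, keep_masks

    def _comparisons(self, cohort, keep_masks, boot_ss) -> list[dict]:
        """Fornix-vs-ILF comparisons per metric class and measure.

        Steiger Z and the dependent-Spearman bootstrap both run on the
        participants surviving the MAD screen for *both* tracts' metrics.
        The predicted direction follows the tract hypothesis: the fornix
        correlation exceeds the ILF one (greater for MD, where positive
        associations are predicted; less for FA, where negative ones are).
        """
        cfg = self.config
        out = []
        streams = iter(boot_ss.spawn(len(MEASURES) * 2))
        for measure in MEASURES:
            base = self._measure_base(cohort, measure)
            for klass in ("md", "fa"):
                fornix, ilf = f"fornix_{klass}", f"ilf_{klass}"
                common = keep_masks[(measure, fornix)] & keep_masks[(measure, ilf)]
                sub = base.loc[common[common].index]
                y = sub[measure].to_numpy()
                r_jk = float(np.corrcoef(y, sub[fornix])[0, 1])
                r_jh = float(np.corrcoef(y, sub[ilf])[0, 1])
                r_kh = float(np.corrcoef(sub[fornix], sub[ilf])[0, 1])
                alternative = METRIC_DIRECTIONS[fornix]
                st = steiger_z_dependent(r_jk, r_jh, r_kh, len(sub), alternative)
                boot = bootstrap_compare_dependent_correlations(
                    y,
                    sub[fornix].to_numpy(),
                    sub[ilf].to_numpy(),
                    n_boot=cfg.n_boot,
                    rng=np.random.default_rng(next(streams)),
                )
                out.append(
                    {
                        "measure": measure,
                        "metric_class": klass,
                        "pair_a": fornix,
                        "pair_b": ilf,
                        "n": int(len(sub)),
                        "alternative": alternative,
                        "steiger": {
                            "z": st.z, "p": st.p,
                            "r_jk": st.r_jk, "r_jh": st.r_jh, "r_kh": st.r_kh,
                        },
                        "bootstrap": {
                            "observed_difference": boot.observed_difference,
                            "ci": [boot.ci_low, boot.ci_high],
                            "n_boot": boot.n_boot,
                            "significant": boot.significant,
                        },
                    }
                )
        return out

    def _partials(self, cohort, keep_masks) -> list[dict]:
        """Partial correlations controlling proportional hippocampal volume
        and, separately, gender, for every (measure, metric) pair."""
        out = []
        for measure in MEASURES:
            base = self._measure_base(cohort, measure)
            for metric, alternative in METRIC_DIRECTIONS.items():
                keep = keep_masks[(measure, metric)]
                sub = base.loc[keep[keep].index]
                for covariate in ("proportional_hc_volume", "gender"):
                    cov = sub[covariate].to_numpy(dtype=float)
                    entry = {
                        "measure": measure,
                        "metric": metric,
                        "covariate": covariate,
                        "alternative": alternative,
                        "n": int(len(sub)),
                    }
                    if np.ptp(cov) == 0:
                        entry["note"] = "covariate constant in subset; skipped"
                    else:
                        pc = partial_correlation(
                            sub[metric].to_numpy(),
                            sub[measure].to_numpy(),
                            cov,
                            alternative,
                        )
                        entry.update(r=pc.estimate, p=pc.p, bf=pc.bf)
                    out.append(entry)
        return out


@dataclass
class NavigationalLearningResults:
    """Fitted pipeline: cohort table, serialisable report, summaries."""

    model: NavigationalLearningModel
    cohort_table: pd.DataFrame
    report: dict

    @property
    def exclusions(self) -> pd.DataFrame:
        return pd.DataFrame(self.report["exclusions"])

    @property
    def learning(self) -> pd.DataFrame:
        return pd.DataFrame(self.report["learning"])

    def correlation(self, measure: str, metric: str) -> dict:
        for entry in self.report["correlations"]:
            if entry["measure"] == measure and entry["metric"] == metric:
                return entry
        raise KeyError((measure, metric))

    def save(self, report_path, cohort_path=None) -> None:
        nio.write_report(self.report, report_path)
        if cohort_path is not None:
            self.cohort_table.to_csv(cohort_path, index=False, float_format="%.12g")

    def plot_learning_curves(self, path=None, max_participants: int = 25):
        from .plotting import plot_learning_curves

        return plot_learning_curves(self, path=path, max_participants=max_participants)

    def summary(self) -> str:
        rep = self.report
        n_total = len(rep["learning"])
        n_excl = sum(e["excluded"] for e in rep["exclusions"])
        lines = [
            "Navigational learning analysis",
            "=" * 46,
            f"participants: {n_total}  behaviourally excluded: {n_excl}",
            f"corrected alpha: {rep['alpha']['corrected_alpha']:.4g} "
            f"(alpha {rep['alpha']['alpha']} / {rep['alpha']['comparisons_per_metric']})",
            "",
            f"{'measure':<24}{'metric':<12}{'n':>4}{'r':>8}{'p':>8}{'BF':>9}  95% BCI",
        ]
        for e in rep["correlations"]:
            pe = e["pearson"]
            lines.append(
                f"{e['measure']:<24}{e['metric']:<12}{e['n']:>4}"
                f"{pe['r']:>8.3f}{pe['p']:>8.3f}{pe['bf']:>9.2f}"
                f"  [{pe['bci'][0]:.2f}, {pe['bci'][1]:.2f}]"
            )
        lines.append("")
        lines.append(f"{'comparison':<34}{'n':>4}{'z':>8}{'p':>8}  bootstrap 95% CI")
        for c in rep["comparisons"]:
            st, bo = c["steiger"], c["bootstrap"]
            lines.append(
                f"{c['measure'] + ': ' + c['pair_a'] + ' vs ' + c['pair_b']:<34}"
                f"{c['n']:>4}{st['z']:>8.2f}{st['p']:>8.3f}"
                f"  [{bo['ci'][0]:.2f}, {bo['ci'][1]:.2f}]"
            )
        return "\n".join(lines)


def run_full_analysis(config: AnalysisConfig) -> NavigationalLearningResults:
    """Build the cohort model from the config's inputs and fit it.

    Inputs are either the latency/metrics CSV paths or a simulation
    parameter set (exactly one of the two must be provided).
    """
    has_files = config.latency_path is not None and config.metrics_path is not None
    if has_files == (config.simulate is not None):
        raise ValueError(
            "config must provide either latency_path+metrics_path or simulate"
        )
    if has_files:
        model = NavigationalLearningModel.from_csv(
            config.latency_path, config.metrics_path, config
        )
    else:
        model = NavigationalLearningModel.from_simulation(config.simulate, config)
    return model.fit()
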