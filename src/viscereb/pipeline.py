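"""End-to-end orchestration: simulate -> preprocess -> invert -> group ->
statistics -> prediction, reproducing the study's result structures on a
synthetic cohort (or, stage by stage, on user data).

The report bundle contains, per group, the empirical-Bayes coupling means
with per-connection posterior probabilities and the pruned model mask
(the connectivity-diagram analogue); the patient-vs-control Welch tests
per coupling; the clinical correlations of the cerebellar self-connection
and the cerebellum -> secondary-visual couplings with acuity scores; the
SVR prediction of the motor score with its permutation-FWE p-values; and
the temporal-SNR comparison between groups.  All randomness derives from
the master seed; re-running a configuration is bit-identical.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as vio
from .ecfit import InvertOptions, PriorSpec, SubjectPosterior, invert_subject
from .groupbayes import (
    GroupDesign,
    clinical_correlate,
    greedy_prune,
    group_ttest,
    peb_fit,
)
from .mvpa import FeatureTable, permutation_fwe
from .regions import PARAM_NAMES, REGIONS, param_index
from .signals import preprocess_subject, tsnr, tsnr_group_test
from .synthcohort import CohortBundle, GeneratorConfig, make_cohort

log = logging.getLogger("viscereb")

#: Fig-4 analogue: (coupling, clinical measure) pairs tested by default
CLINICAL_PAIRS: tuple[tuple[str, str], ...] = (
    ("self_C", "bcva_pre_od"),
    ("self_C", "bcva_pre_os"),
    ("C->SV_L", "recovery_os"),
    ("C->SV_R", "recovery_od"),
)


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce one full run."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    n_patients: int = 27
    n_controls: int = 11
    band: tuple[float, float] = (0.0, 0.08)
    prior: PriorSpec = field(default_factory=PriorSpec)
    invert: InvertOptions = field(default_factory=InvertOptions)
    mvpa_n_perm: int = 1000
    mvpa_label: str = "joa_pre"
    master_seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class ReportBundle:
    group_graphs: dict
    group_difference: dict | None
    clinical_correlations: dict
    mvpa_summary: dict | None
    tsnr_summary: dict
    provenance: dict
    posteriors: dict[str, list[SubjectPosterior]] = field(default_factory=dict)
    cohort: CohortBundle | None = None


def _write_parameter_table(path, bundle: "ReportBundle") -> None:
    """Plot-ready per-parameter TSV: group means, posterior probabilities,
    retention flags and the Welch contrast (the connectivity-diagram and
    violin-plot analogue)."""
    import pandas as pd
    rows = {"parameter": list(PARAM_NAMES)}
    for grp, g in bundle.group_graphs.items():
        rows[f"mean_{grp}"] = [g["mean"][nm] for nm in PARAM_NAMES]
        rows[f"pp_{grp}"] = [g["pp"][nm] for nm in PARAM_NAMES]
        rows[f"retained_{grp}"] = [g["retained"][nm] for nm in PARAM_NAMES]
    if bundle.group_difference is not None:
        tab = bundle.group_difference["table"]
        rows["welch_t"] = tab["t"]
        rows["welch_p"] = tab["p"]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_pipeline(config: RunConfig = RunConfig(),
                 out_dir: str | Path | None = None,
                 keep_cohort: bool = False) -> ReportBundle:
    """Execute the full analysis on a synthetic cohort.

    Stages: cohort simulation, temporal preprocessing + eigenvariate
    extraction, subject-level inversion, per-group empirical-Bayes fusion
    with greedy pruning and posterior-probability calls, Welch contrasts,
    clinical correlations, SVR prediction with permutation FWE, and the
    temporal-SNR check.  Failures carry the stage name; with
    ``n_controls = 0`` the group-difference stage is skipped with a
    logged notice and everything else still runs.
    """
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    chash = vio.config_hash(config.to_dict())
    seeds = {"cohort": config.master_seed}

    stage = "simulate"
    try:
        cohort = make_cohort(config.n_patients, config.n_controls,
                             config.generator, config.master_seed)

        stage = "preprocess"
        acq = config.generator.acquisition
        series = []
        for s in cohort.subjects:
            series.append(preprocess_subject(
                s.voxel_blocks, s.nuisance, n_drop=acq.n_drop,
                band=config.band, tr_seconds=acq.tr_seconds))

        stage = "invert"
        posteriors: dict[str, list[SubjectPosterior]] = {"patient": [], "control": []}
        for s, ts in zip(cohort.subjects, series):
            post = invert_subject(ts, prior=config.prior, opts=config.invert)
            posteriors[s.group].append(post)
            if out is not None:
                idx = len(posteriors[s.group]) - 1
                vio.save_posterior(out / f"posterior_{s.group}_{idx:02d}.json", post)

        stage = "group"
        group_graphs = {}
        for grp, posts in posteriors.items():
            if len(posts) < 2:
                log.info("skipping group-level fit for %s (n=%d)", grp, len(posts))
                continue
            gm = peb_fit(posts, GroupDesign.intercept_only(len(posts)))
            rm = greedy_prune(gm)
            group_graphs[grp] = {
                "n": len(posts),
                "mean": dict(zip(PARAM_NAMES, gm.beta_mean[0])),
                "pp": dict(zip(PARAM_NAMES, rm.pp)),
                "retained": dict(zip(PARAM_NAMES, rm.mask.astype(bool))),
                "significant": dict(zip(
                    PARAM_NAMES, (rm.mask & (rm.pp > 0.95)).astype(bool))),
                "between_subject_var": dict(zip(PARAM_NAMES, gm.between_subject_var)),
                "free_energy": gm.free_energy,
                "prune_delta_f": rm.delta_f,
            }

        stage = "group_difference"
        group_difference = None
        pat_means = np.array([p.mean.values for p in posteriors["patient"]])
        if len(posteriors["control"]) >= 2 and len(posteriors["patient"]) >= 2:
            con_means = np.array([p.mean.values for p in posteriors["control"]])
            table = group_ttest(pat_means, con_means)
            group_difference = {
                "table": table.to_dict(orient="list"),
                "significant": table.loc[table.p < 0.05, "parameter"].tolist(),
            }
        else:
            log.info("group-difference stage skipped (need >=2 subjects per group)")

        stage = "clinical"
        clinical = {}
        pats = cohort.patients
        if pats and pats[0].clinical is not None and len(pats) >= 3:
            for coupling, measure in CLINICAL_PAIRS:
                x = pat_means[:, param_index(coupling)]
                y = np.array([getattr(s.clinical, measure) for s in pats])
                clinical[f"{coupling}~{measure}"] = clinical_correlate(x, y)

        stage = "mvpa"
        mvpa_summary = None
        if len(pats) >= 3 and pats[0].clinical is not None:
            labels = np.array([getattr(s.clinical, config.mvpa_label) for s in pats])
            table = FeatureTable(pat_means, labels)
            res = permutation_fwe(table, n_perm=config.mvpa_n_perm,
                                  seed=config.master_seed + 777)
            seeds["mvpa"] = config.master_seed + 777
            mvpa_summary = {
                "fractions": res.fractions.tolist(),
                "r_per_fraction": res.r_per_fraction.tolist(),
                "p_fwe_per_fraction": res.p_fwe_per_fraction.tolist(),
                "best_fraction": res.best_fraction,
                "best_r": res.best_r,
                "min_p_fwe": res.min_p_fwe,
                "n_features_best": int(max(1, round(res.best_fraction
                                                    * len(PARAM_NAMES)))),
                "sensitivity_map": res.sensitivity_map,
                "n_perm": res.n_perm,
            }

        stage = "tsnr"
        tsnr_vals: dict[str, list[float]] = {"patient": [], "control": []}
        for s in cohort.subjects:
            vals = [tsnr(s.voxel_blocks[r].data.mean(axis=0)) for r in REGIONS]
            tsnr_vals[s.group].append(float(np.mean(vals)))
        tsnr_summary = {
            "mean_patient": (float(np.mean(tsnr_vals["patient"]))
                             if tsnr_vals["patient"] else None),
            "mean_control": (float(np.mean(tsnr_vals["control"]))
                             if tsnr_vals["control"] else None),
        }
        if len(tsnr_vals["patient"]) >= 2 and len(tsnr_vals["control"]) >= 2:
            t, p = tsnr_group_test(tsnr_vals["patient"], tsnr_vals["control"])
            tsnr_summary.update({"welch_t": t, "welch_p": p})
    except Exception as err:
        raise RuntimeError(f"pipeline failed in stage '{stage}': {err}") from err

    bundle = ReportBundle(
        group_graphs=group_graphs,
        group_difference=group_difference,
        clinical_correlations=clinical,
        mvpa_summary=mvpa_summary,
        tsnr_summary=tsnr_summary,
        provenance={"config_hash": chash, "config": config.to_dict(),
                    "seeds": seeds, "n_subjects": len(cohort.subjects)},
        posteriors=posteriors,
        cohort=cohort if keep_cohort else None,
    )
    if out is not None:
        _write_parameter_table(out / "parameter_table.tsv", bundle)
        vio.save_json(out / "report.json", {
            "group_graphs": bundle.group_graphs,
            "group_difference": bundle.group_difference,
            "clinical_correlations": bundle.clinical_correlations,
            "mvpa_summary": bundle.mvpa_summary,
            "tsnr_summary": bundle.tsnr_summary,
            "provenance": bundle.provenance,
        })
    return bundle
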