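"""End-to-end drivers tying the stages into the full analysis pipeline.

generate (or read) scan paths -> per-subject-per-block inversion -> PEB over
blocks -> Bayesian model reduction over the 256 effect combinations ->
Bayesian model averages -> canonical correlation against behaviour.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .generative_model import SceneModel, build_scene_model
from .heuristics import estimate_heuristic_map
from .invert import (
    PARAM_NAMES,
    FitPriors,
    GaussianPosterior,
    fit_subject,
)
from .io import behaviour_from_frame, frame_to_trials
from .peb import EFFECT_NAMES, ModelSpace, PEBModel, bma, peb_fit, search_model_space
from .phenotype import CVAResult, cva


def fit_cohort(
    frame: pd.DataFrame,
    priors: FitPriors | None = None,
    model: SceneModel | None = None,
) -> dict[tuple[str, int], GaussianPosterior]:
    """Invert every (subject, block) cell of a scan-path frame.

    Each subject's heuristic map is estimated from their own saccade
    sequences (all blocks pooled), as the fixed-form policy is
    subject-specific.
    """
    if model is None:
        model = build_scene_model()
    grouped = frame_to_trials(frame)
    subjects = sorted({s for s, _ in grouped})
    fits: dict[tuple[str, int], GaussianPosterior] = {}
    for subj in subjects:
        paths = [
            [loc for _, loc, _ in t.path]
            for (s, _), trials in grouped.items()
            if s == subj
            for t in trials
        ]
        H = estimate_heuristic_map(paths)
        for (s, b), trials in grouped.items():
            if s != subj:
                continue
            fits[(s, b)] = fit_subject(trials, priors, model=model, H=H)
    return fits


def peb_cohort(
    fits: dict[tuple[str, int], GaussianPosterior],
) -> tuple[list[str], list[PEBModel]]:
    """One PEB model per subject from their block-wise posteriors."""
    subjects = sorted({s for s, _ in fits})
    pebs = []
    from .peb import peb_design

    for subj in subjects:
        blocks = sorted(b for s, b in fits if s == subj)
        pebs.append(
            peb_fit([fits[(subj, b)] for b in blocks], X=peb_design(len(blocks)))
        )
    return subjects, pebs


def bma_table(
    subjects: list[str], pebs: list[PEBModel], space: ModelSpace
) -> pd.DataFrame:
    """Per-subject Bayesian model averages of the 8 second-level effects."""
    rows = []
    for si, subj in enumerate(subjects):
        avg = bma(space, space.reduced_posteriors[si])
        rows.append({"subject_id": subj, **dict(zip(EFFECT_NAMES, avg.mu))})
    return pd.DataFrame(rows).set_index("subject_id")


#: BMA columns entering the phenotyping matrix: the four constants plus the
#: two preference decay terms (the effects the winning model retains)
PHENOTYPE_EFFECTS = tuple(
    [f"{p}_const" for p in PARAM_NAMES] + ["ln_C_cor_decay", "ln_C_q_decay"]
)


@dataclass
class PipelineResult:
    fits: dict[tuple[str, int], GaussianPosterior]
    subjects: list[str]
    pebs: list[PEBModel]
    model_space: ModelSpace
    bma: pd.DataFrame
    behaviour: pd.DataFrame
    cva: CVAResult | None


def run_pipeline(
    frame: pd.DataFrame,
    priors: FitPriors | None = None,
    model: SceneModel | None = None,
    with_cva: bool = True,
) -> PipelineResult:
    """Run inversion, PEB, BMR/BMA and CVA on a scan-path frame."""
    fits = fit_cohort(frame, priors, model)
    subjects, pebs = peb_cohort(fits)
    space = search_model_space(pebs)
    averages = bma_table(subjects, pebs, space)
    behaviour = behaviour_from_frame(frame).loc[subjects]
    result = PipelineResult(
        fits=fits,
        subjects=subjects,
        pebs=pebs,
        model_space=space,
        bma=averages,
        behaviour=behaviour,
        cva=None,
    )
    if with_cva and len(subjects) > 3:
        X = parameter_matrix(averages)
        result.cva = cva(X, behaviour)
    return result


def parameter_matrix(averages: pd.DataFrame) -> pd.DataFrame:
    """Six-column phenotyping matrix: four constants + the two C decay terms."""
    return averages[list(PHENOTYPE_EFFECTS)].copy()
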