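"""End-to-end convenience wrapper over the analysis stages.

`run_choice_pipeline` takes a session plus rotated latent trajectories
(stimulus axis first) and produces, for each axis set — stimulus axis,
non-stimulus axes, all latent dimensions, and the raw population
counts — the held-out choice mapping, its choice probability, and the
nested likelihood-ratio tests, after weak-trial selection and pulse
residualization.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np

from .choice import (
    CPResult,
    ChoiceMapping,
    NestedLRResult,
    ResidualActivity,
    WeakTrialSet,
    choice_probability,
    fit_choice_decoder,
    nested_lr_tests,
    regress_out_pulses,
    select_weak_trials,
)
from .session import SessionData, bin_counts, rebin

__all__ = ["ChoicePipelineResult", "run_choice_pipeline"]

AXIS_SETS = ("stimulus", "non_stimulus", "all_latent", "population")


@dataclass
class ChoicePipelineResult:
    weak: WeakTrialSet
    residual_latent: ResidualActivity
    residual_population: ResidualActivity
    mappings: Dict[str, ChoiceMapping]
    cp: Dict[str, CPResult]
    lr: NestedLRResult
    choices: np.ndarray

    def summary(self) -> str:
        lines = [
            "Choice-probability decomposition",
            "=" * 40,
            f"weak trials: {self.weak.n_trials} "
            f"(levels {self.weak.coherence_levels_included}, "
            f"correct rate {self.weak.achieved_correct_rate:.3f})",
            "",
            "axis set        CP      n",
        ]
        for name, res in self.cp.items():
            lines.append(f"{name:<14s} {res.cp:.3f}  {res.n_trials}")
        lines += [
            "",
            f"LR1 (+non-stimulus) = {self.lr.lr1:.4g}, p = {self.lr.p1:.3g}",
            f"LR2 (+population)   = {self.lr.lr2:.4g}, p = {self.lr.p2:.3g}",
        ]
        return "\n".join(lines)


def run_choice_pipeline(session: SessionData, rotated_latents: np.ndarray,
                        threshold: float = 0.65, min_trials: int = 100,
                        bin_ms: int = 100, seed: int = 0,
                        weak: Optional[WeakTrialSet] = None
                        ) -> ChoicePipelineResult:
    """Weak trials -> residualization -> decoders -> CP -> nested LR tests.

    ``rotated_latents`` is (n_trials, T, D) with the stimulus axis in
    column 0 (output of the stimulus-axis rotation).
    """
    if weak is None:
        weak = select_weak_trials(session, threshold, min_trials)
    idx = weak.trial_indices
    if len(idx) == 0:
        raise ValueError("no weak trials")
    choices = session.choice[idx].astype(int)
    pulses = session.pulses[idx]

    lat100 = rebin(np.asarray(rotated_latents, dtype=float)[idx], bin_ms)
    pop100 = rebin(session.spikes[idx].astype(float), bin_ms)
    res_lat = regress_out_pulses(lat100, pulses, trial_indices=idx)
    res_pop = regress_out_pulses(pop100, pulses, trial_indices=idx)

    D = rotated_latents.shape[2]
    subsets = {
        "stimulus": res_lat.subset([0]),
        "non_stimulus": res_lat.subset(list(range(1, D))),
        "all_latent": res_lat,
        "population": res_pop,
    }
    mappings, cps = {}, {}
    for name, res in subsets.items():
        _, mapping = fit_choice_decoder(res, choices, seed=seed, axis_set=name,
                                        session_id=session.session_id)
        mappings[name] = mapping
        cps[name] = choice_probability(mapping, choices, axis_set=name)
    lr = nested_lr_tests(mappings["stimulus"], mappings["non_stimulus"],
                         mappings["population"], choices)
    return ChoicePipelineResult(weak=weak, residual_latent=res_lat,
                                residual_population=res_pop, mappings=mappings,
                                cp=cps, lr=lr, choices=choices)
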