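"""Monte-Carlo validation of the pipeline against its own generative model.

Each routine here exercises the full stack (schedule -> simulated events ->
exclusion filters -> labelled ISIs -> statistics) and measures an
operating characteristic: type-I error calibration of the permutation
tests under the null phenotype, recovery of injected phenotypes, saccade
detection round-trip accuracy, counterbalancing of absolute-location
effects, and dominant-component classification.  Problem sizes default to
modest session counts chosen so the whole battery runs in a few minutes on
one core; all randomness descends from a single seed.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .decomposition import cell_means, ms_decomposition, normalize_ms
from .model import InducerEffectModel
from .paradigm import build_layout, make_schedule, n_target_steps, reward_window
from .preprocess import REL_CATEGORIES, detect_saccades
from .simulate import PhenotypeParams, get_phenotype, render_trace, sample_session
from .vectorstats import classify_orientation, permutation_test

__all__ = [
    "design_constants",
    "null_calibration",
    "phenotype_recovery",
    "detection_roundtrip",
    "counterbalance_spread",
    "dominance_rates",
]


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def design_constants() -> dict:
    """The task's printed design constants, recomputed from the layout/schedule."""
    layout = build_layout(6, 7.0)
    human = make_schedule(100, "human_2_of_3", 600, seed=0)
    monkey = make_schedule(7, "monkey_6_of_7", 400, seed=0)
    return {
        "target_steps_soa400": n_target_steps(12, 400),
        "target_steps_soa600": n_target_steps(12, 600),
        "reward_halfwidth_ms_soa400": reward_window(400, 0.2),
        "reward_halfwidth_ms_soa600": reward_window(600, 0.2),
        "human_trials_with_inducer": sum(t.has_inducer for t in human),
        "human_trials_without_inducer": sum(not t.has_inducer for t in human),
        "monkey_inducer_trials_per_7": sum(t.has_inducer for t in monkey),
        "adjacent_landmark_spacing_deg": layout.adjacent_distance,
    }


def _labeled_session(
    phenotype: PhenotypeParams,
    n_trials: int,
    soa_ms: float,
    seed: int,
    inducer_balance: str = "across",
):
    schedule = make_schedule(
        n_trials, "all", soa_ms, seed=seed, inducer_balance=inducer_balance
    )
    events = sample_session(schedule, phenotype, seed=seed + 1)
    return InducerEffectModel.from_events(events, "predictive").data


def null_calibration(
    n_sessions: int = 500,
    n_perm: int = 200,
    n_trials: int = 30,
    soa_ms: float = 600.0,
    seed: int = 0,
) -> dict:
    """Empirical type-I error of both permutation modes under the null.

    Simulates inducer-naive (NULL-phenotype) sessions and counts how often
    each mode declares significance at the nominal 5% level.
    """
    seeds = _child_seeds(seed, 2 * n_sessions)
    phen = get_phenotype("NULL")
    seq_hits = io_hits = 0
    for i in range(n_sessions):
        lab = _labeled_session(phen, n_trials, soa_ms, seeds[2 * i])
        seq_hits += permutation_test(
            lab, mode="sequence", n_perm=n_perm, seed=seeds[2 * i + 1]
        ).significant
        io_hits += permutation_test(
            lab, mode="inside_outside", n_perm=n_perm, seed=seeds[2 * i + 1] + 1
        ).significant
    return {
        "sequence_rejection_rate": seq_hits / n_sessions,
        "inside_outside_rejection_rate": io_hits / n_sessions,
        "n_sessions": n_sessions,
        "n_perm": n_perm,
    }


def phenotype_recovery(
    phenotype_name: str,
    n_replicates: int = 50,
    n_trials: int = 200,
    n_perm: int = 200,
    soa_ms: float = 600.0,
    seed: int = 0,
) -> dict:
    """Fraction of replicate sessions recovering the injected phenotype.

    Boundary-delay phenotypes count as recovered when the sequence
    statistic is significant *and* the resultant classifies to the injected
    location; the inside-slow phenotype when the inside-outside statistic
    is significant and positive.
    """
    phen = get_phenotype(phenotype_name)
    expected_loc = phen.boundary_delay[0] if phen.boundary_delay else None
    seeds = _child_seeds(seed, 2 * n_replicates)
    hits = 0
    for i in range(n_replicates):
        lab = _labeled_session(phen, n_trials, soa_ms, seeds[2 * i])
        if expected_loc is not None:
            res = permutation_test(
                lab, mode="sequence", n_perm=n_perm, seed=seeds[2 * i + 1]
            )
            hits += res.significant and classify_orientation(res.observed) == expected_loc
        else:
            res = permutation_test(
                lab, mode="inside_outside", n_perm=n_perm, seed=seeds[2 * i + 1]
            )
            hits += res.significant and res.statistic > 0
    return {
        "recovery_rate": hits / n_replicates,
        "n_replicates": n_replicates,
        "n_trials": n_trials,
    }


def detection_roundtrip(
    n_trials: int = 100,
    soa_ms: float = 400.0,
    sample_rate: float = 1000.0,
    tolerance_ms: float = 2.0,
    seed: int = 0,
) -> dict:
    """Render-and-redetect round trip over whole simulated trials.

    Returns the fraction of injected saccade onsets recovered within
    ``tolerance_ms`` and the count of spurious detections.
    """
    schedule = make_schedule(n_trials, "all", soa_ms, seed=seed)
    events = sample_session(schedule, get_phenotype("NULL"), seed=seed + 1)
    n_total = n_hit = n_detected = 0
    for trial in schedule:
        ev = events[events["trial_id"] == trial.trial_id]
        trace = render_trace(trial, ev, sample_rate=sample_rate)
        det = detect_saccades(trace)["onset_ms"].to_numpy()
        truth = np.sort(ev["onset_ms"].to_numpy())
        n_total += len(truth)
        n_detected += len(det)
        if len(det):
            for t_on in truth:
                if np.min(np.abs(det - t_on)) <= tolerance_ms:
                    n_hit += 1
    return {
        "recovery_fraction": n_hit / n_total,
        "spurious_detections": n_detected - n_hit,
        "n_onsets": n_total,
    }


def counterbalance_spread(
    n_trials: int = 120,
    soa_ms: float = 600.0,
    seed: int = 0,
    abs_location_offsets: tuple = (0.0, 15.0, -10.0, 20.0, -15.0, 5.0),
) -> dict:
    """Spread of relative-label ISI means under pure absolute-location effects.

    With the inducer balanced within the session, absolute-location timing
    structure must average out of the relative-location sorting; returns
    the largest pairwise mean difference in units of its standard error.
    """
    phen = PhenotypeParams(abs_location_offsets=abs_location_offsets)
    lab = _labeled_session(phen, n_trials, soa_ms, seed, inducer_balance="within")
    g = lab.groupby("relative_label")["isi_ms"]
    means, sems = g.mean(), g.sem()
    worst = 0.0
    worst_ms = 0.0
    for i, a in enumerate(REL_CATEGORIES):
        for b in REL_CATEGORIES[i + 1 :]:
            z = abs(means[a] - means[b]) / float(np.hypot(sems[a], sems[b]))
            worst = max(worst, z)
            worst_ms = max(worst_ms, abs(means[a] - means[b]))
    return {
        "max_pairwise_diff_se_units": worst,
        "max_pairwise_diff_ms": worst_ms,
        "n_isis": len(lab),
    }


def dominance_rates(
    n_replicates: int = 30,
    n_trials: int = 200,
    soa_ms: float = 600.0,
    seed: int = 0,
) -> dict:
    """Dominant-component classification rates per simulated phenotype.

    Sequence-delay phenotypes should classify as sequence-dominant and the
    inside-slow phenotype as inside-outside-dominant, mirroring the
    monkey-like clusters on the ternary plot.
    """
    expectations = {
        "BOUNDARY_DELAY_3": "sequence",
        "MIDDLE_DELAY_2": "sequence",
        "INSIDE_SLOW": "inside_outside",
    }
    out: dict = {"n_replicates": n_replicates}
    for k, (name, expected) in enumerate(expectations.items()):
        seeds = _child_seeds(seed + 1000 * k, n_replicates)
        phen = get_phenotype(name)
        hits = 0
        for s in seeds:
            lab = _labeled_session(phen, n_trials, soa_ms, s)
            norm = normalize_ms(ms_decomposition(cell_means(lab)))
            hits += norm.dominant == expected
        out[name] = hits / n_replicates
    return out
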