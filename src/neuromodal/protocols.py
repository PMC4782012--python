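"""The study protocols: sweeps, repeated trials, and their summary statistics.

Each function runs a complete, self-contained experiment protocol at desk
scale and returns the quantities the analyses report:

* :func:`ratio_sweep` -- feed-forward amplitude-ratio sweep with weighted
  linear fits of the converged input/output weight ratios;
* :func:`two_mass_convergence` -- repeated seeded closed-loop trials on
  the linear plant with randomized initial weights/concentrations;
* :func:`leg_convergence` -- the same for the hopping leg, including the
  dominant principal component of the joint trajectory and the converged
  weight-vector norms;
* :func:`jump_plateau` -- fixed-weight-ratio sweep of jump height at
  constant inserted energy (constant weight norm);
* :func:`network_size_comparison` -- apex-height fluctuation of the small
  versus the enlarged network with the one-sided F-test.

Protocol scales (durations, speedup factors, averaging windows) are fixed
here as the package's desk-scale realization of the full-length study
protocols; see the methods note for the scaling rationale.  All
randomness derives from the single ``seed`` argument.
"""

from __future__ import annotations

import numpy as np

from . import analysis
from .config import feedforward_config, leg_config, two_mass_config
from .engine import run_feedforward, run_leg, run_two_mass

__all__ = [
    "ratio_sweep",
    "two_mass_convergence",
    "leg_convergence",
    "jump_plateau",
    "network_size_comparison",
]

#: averaging window before the end of each run (s), as in the analyses
WINDOW = 50.0


def _tail_ratios(rec, duration, window=WINDOW):
    w = rec["weights"]
    c = rec["serotonin"]
    tw = w[w.t > duration - window]
    tc = c[c.t > duration - window]
    wr = tw.w1 / tw.w2
    cr = tc.conc1 / tc.conc2
    return wr.mean(), wr.std(), cr.mean(), cr.std()


def ratio_sweep(seed: int = 0, sigma: float = 0.1, n_ratios: int = 19,
                duration: float | None = None) -> dict:
    """Feed-forward sweep of the drive amplitude ratio a1/a2.

    Runs one open-loop simulation per ratio in [0.05, 0.95], averages the
    converged synaptic and neuromodulatory weight ratios over the final
    window, and fits both against the programmed ratio with a weighted
    linear least-squares fit (weights = the within-window fluctuation).
    """
    ratios = np.linspace(0.05, 0.95, n_ratios)
    rows = []
    for i, r in enumerate(ratios):
        cfg = feedforward_config(a_ratio=float(r), sigma=sigma,
                                 seed=seed * 1009 + i, duration=duration)
        rec = run_feedforward(cfg)
        rows.append(_tail_ratios(rec, cfg.duration))
    rows = np.asarray(rows)
    fit_stdp = analysis.weighted_linear_fit(
        ratios, rows[:, 0], np.maximum(rows[:, 1], 1e-3))
    fit_nm = analysis.weighted_linear_fit(
        ratios, rows[:, 2], np.maximum(rows[:, 3], 1e-3))
    return {
        "ratios": ratios,
        "w_ratio": rows[:, 0], "w_ratio_sd": rows[:, 1],
        "nm_ratio": rows[:, 2], "nm_ratio_sd": rows[:, 3],
        "fit_stdp": fit_stdp, "fit_nm": fit_nm,
    }


def two_mass_convergence(seed: int = 0, n_trials: int = 10,
                         duration: float = 400.0) -> dict:
    """Repeated two-mass closed-loop trials; converged weight ratios.

    Trial 0 starts from the tabulated initial weights and concentrations;
    the remaining trials draw initial synaptic weights from [0.8, 1.2] and
    initial concentrations from [6, 60] nM.
    """
    rng = np.random.default_rng(seed)
    wrs, crs = [], []
    for trial in range(n_trials):
        if trial == 0:
            w0, c0 = (0.7, 0.4), (50.0, 20.0)
        else:
            w0 = tuple(rng.uniform(0.8, 1.2, 2))
            c0 = tuple(rng.uniform(6.0, 60.0, 2))
        cfg = two_mass_config(seed=seed * 1013 + trial, duration=duration,
                              w_stdp_0=w0, conc0=c0)
        rec = run_two_mass(cfg)
        wr, _, cr, _ = _tail_ratios(rec, duration)
        wrs.append(wr)
        crs.append(cr)
    wrs, crs = np.array(wrs), np.array(crs)
    return {
        "w_ratio_trials": wrs, "nm_ratio_trials": crs,
        "w_ratio": wrs.mean(), "w_ratio_sd": wrs.std(ddof=1),
        "nm_ratio": crs.mean(), "nm_ratio_sd": crs.std(ddof=1),
    }


def leg_convergence(seed: int = 0, n_trials: int = 10,
                    duration: float = 150.0) -> dict:
    """Repeated hopping-leg trials; ratios, trajectory PC and weight norms."""
    rng = np.random.default_rng(seed)
    wrs, crs, pcs = [], [], []
    norms = None
    for trial in range(n_trials):
        if trial == 0:
            w0, c0 = (1.0, 1.0), (18.0, 6.0)
        else:
            w0 = tuple(rng.uniform(0.8, 1.2, 2))
            c0 = tuple(rng.uniform(6.0, 60.0, 2))
        cfg = leg_config(seed=seed * 1019 + trial, duration=duration,
                         w_stdp_0=w0, conc0=c0)
        rec = run_leg(cfg)
        w = rec["weights"]
        c = rec["serotonin"]
        tw = w[w.t > duration - WINDOW]
        tc = c[c.t > duration - WINDOW]
        wrs.append((tw.w1 / tw.w2).mean())
        crs.append((tc.conc1 / tc.conc2).mean())
        tr = rec["trajectory"]
        pc = analysis.dominant_principal_component(
            tr[tr.t > duration - WINDOW][["phi1", "phi2"]].to_numpy())
        pcs.append(pc[0] / pc[1])
        if trial == 0:
            norms = {
                "stdp": float(np.hypot(tw.w1.mean(), tw.w2.mean())),
                "nm": float(cfg.serotonin.c_NM
                            * np.hypot(tc.conc1.mean(), tc.conc2.mean())),
            }
    wrs, crs, pcs = np.array(wrs), np.array(crs), np.array(pcs)
    return {
        "w_ratio_trials": wrs, "nm_ratio_trials": crs, "pc_ratio_trials": pcs,
        "w_ratio": wrs.mean(), "w_ratio_sd": wrs.std(ddof=1),
        "nm_ratio": crs.mean(), "nm_ratio_sd": crs.std(ddof=1),
        "pc_ratio": pcs.mean(), "pc_ratio_sd": pcs.std(ddof=1),
        "norms": norms,
    }


def jump_plateau(seed: int = 0, stdp_norm: float = 1.8, nm_norm: float = 1.85,
                 duration: float = 20.0) -> dict:
    """Jump height versus fixed weight ratio at constant inserted energy.

    Both weight vectors are frozen at the given norms while their common
    ratio w1/w2 sweeps 0.05-1.5 in steps of 0.03; with equal joint
    stiffnesses the constant norm keeps the inserted energy per cycle
    constant.  Each run lasts ``duration`` seconds and reports the mean
    apex height of the final 20 jumps.
    """
    ratios = np.arange(0.05, 1.51, 0.03)
    means = np.full(ratios.shape, np.nan)
    for i, r in enumerate(ratios):
        u = np.array([r, 1.0]) / np.hypot(r, 1.0)
        cfg = leg_config(seed=seed * 1021 + i, duration=duration)
        rec = run_leg(cfg, fixed_weights=tuple(stdp_norm * u),
                      fixed_nm=tuple(nm_norm * u))
        tk = rec["trunk"]
        try:
            js = analysis.jump_metrics(tk.t.to_numpy(), tk.h.to_numpy(),
                                       tk.contact.to_numpy())
            means[i] = np.mean(js.apex_heights[-20:])
        except ValueError:
            means[i] = np.nan  # grounded: no jumps at this ratio
    good = np.isfinite(means)
    lo, hi = analysis.plateau_ratios(ratios[good], means[good])
    return {"ratios": ratios, "mean_heights": means,
            "plateau_low": lo, "plateau_high": hi}


def network_size_comparison(seed: int = 0, duration: float = 50.0,
                            window: tuple = (30.0, 50.0)) -> dict:
    """Apex-height fluctuation of the small versus the enlarged network.

    Both runs use the full-scale (uncompressed) protocol for 50 s with the
    synaptic weights held at their initial values, so that the
    fluctuation measure reflects the Poisson noise of the pools rather
    than a learning transient sweeping through the window; the
    serotonergic gains stay dynamic.  Returns the apex standard deviations
    in the 30-50 s window and the one-sided F-test (with assumption
    checks) that the small network fluctuates more.
    """
    out = {}
    jumps = {}
    for label, large in (("small", False), ("large", True)):
        cfg = leg_config(seed=seed * 1031 + int(large), duration=duration,
                         speedup=1.0, large=large)
        rec = run_leg(cfg, fixed_weights=cfg.w_stdp_0)
        tk = rec["trunk"]
        sel = (tk.t >= window[0]) & (tk.t <= window[1])
        js = analysis.jump_metrics(tk.t[sel].to_numpy(), tk.h[sel].to_numpy(),
                                   tk.contact[sel].to_numpy())
        jumps[label] = js
        out[f"sd_{label}_mm"] = js.std * 1e3
        out[f"mean_{label}_mm"] = js.mean * 1e3
        out[f"n_{label}"] = len(js.apex_heights)
    ftest = analysis.variance_comparison(
        jumps["small"].apex_heights, jumps["large"].apex_heights,
        jumps["small"].apex_times, jumps["large"].apex_times)
    out.update({"F": ftest["F"], "p": ftest["p"], "checks": ftest["checks"]})
    return out
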