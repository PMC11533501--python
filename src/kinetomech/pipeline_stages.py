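"""Simulate -> analyze chains for each assay, at the study conditions.

Each stage generates synthetic data with the generator defaults that
emulate the published experiments (site counts, interval counts, event
counts, noise levels), runs the corresponding analysis modules, writes
tables under the output directory, and returns a metrics dict. Problem
sizes match the experimental sample sizes: ~3,400 DNAs over 9 fields
for colocalization, 74–128 intervals per component for nanometry,
105/123 sliding events and 43/26 rupture events for trap mechanics.
"""

from __future__ import annotations

import zlib
from pathlib import Path

import numpy as np
import pandas as pd

from . import bleachsteps, cosmos, flipflop, simgen, trapmech
from .simgen import TOWARD_MINUS, TOWARD_PLUS
from .statcore import ks_two_sample


def _child_seed(seed: int, tag: str) -> int:
    """Deterministic (process-independent) per-stage seed below 2**31."""
    mixed = np.random.SeedSequence([seed, zlib.crc32(tag.encode())])
    return int(mixed.generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# CoSMoS colocalization + capture polarity
# ---------------------------------------------------------------------------


def _detect_field(img, channel, fov, cfg):
    det = cosmos.detect_spots(img, cfg, channel=channel)
    det = det.assign(fov=fov)
    return det


def stage_cosmos(seed: int, params: dict, outdir: Path, log) -> dict:
    """Two-channel field simulation -> detection -> registration -> coloc.

    Defaults model the inner-kinetochore (Ndc10-like) run: 9 fields of
    ~380 DNA sites each (>3,400 total) at 28% true colocalization, plus
    a negative-control run (0% true colocalization, false spots only)
    and a polarity-marked capture experiment (8 replicates, 196
    filaments, 82.7% true plus-end capture).
    """
    p_coloc = params.get("p_coloc", 0.28)
    n_fov = params.get("n_fov", 9)
    n_sites = params.get("n_sites", 380)
    radius = params.get("radius", 1.5)
    det_cfg = cosmos.DetectionConfig(threshold=params.get("threshold", 50.0))
    rng = np.random.default_rng(_child_seed(seed, "cosmos"))

    # registration from a dense fiducial field (every site in both channels)
    fid_cfg = simgen.CosmosFieldConfig(
        field_size=512, n_sites=150, p_coloc=1.0, false_spot_density=0.0,
        seed=_child_seed(seed, "fiducials"),
    )
    (ref_img, mov_img), fid_truth = simgen.make_cosmos_field(fid_cfg)
    ref_spots = cosmos.detect_spots(ref_img, det_cfg)
    mov_spots = cosmos.detect_spots(mov_img, det_cfg)
    # pair fiducials by proximity of the moving spot to each reference spot
    from scipy.spatial import cKDTree

    tree = cKDTree(mov_spots[["x", "y"]].to_numpy())
    d, idx = tree.query(ref_spots[["x", "y"]].to_numpy(), k=1)
    keep = d < 3.0
    regmap = cosmos.fit_registration(
        ref_spots[["x", "y"]].to_numpy()[keep],
        mov_spots[["x", "y"]].to_numpy()[idx[keep]],
    )
    log.info("registration rms=%.4f px from %d fiducials",
             regmap.residual_rms, regmap.n_fiducials)

    def run_fields(p, tag):
        ref_all, tgt_all = [], []
        for fov in range(n_fov):
            cfg = simgen.CosmosFieldConfig(
                field_size=512, n_sites=n_sites, p_coloc=p,
                seed=_child_seed(seed, f"{tag}-{fov}"),
            )
            (dna, gfp), _ = simgen.make_cosmos_field(cfg)
            ref = _detect_field(dna, "dna", fov, det_cfg)
            tgt = _detect_field(gfp, "gfp", fov, det_cfg)
            reg_xy = cosmos.apply_registration(
                regmap.inverse(), tgt[["x", "y"]].to_numpy()
            )
            tgt = tgt.assign(x=reg_xy[:, 0], y=reg_xy[:, 1])
            ref_all.append(ref)
            tgt_all.append(tgt)
        return cosmos.colocalization_fraction(
            pd.concat(ref_all, ignore_index=True),
            pd.concat(tgt_all, ignore_index=True),
            radius=radius,
        )

    coloc = run_fields(p_coloc, "field")
    negative = run_fields(0.0, "negctrl")
    coloc.per_fov.to_csv(outdir / "coloc_per_fov.csv", index=False)

    # polarity-marked capture: 8 replicates, 196 filaments, p = 162/196
    p_plus = params.get("p_plus_capture", 162.0 / 196.0)
    n_per_exp = params.get("filaments_per_experiment", (25, 25, 25, 25, 24, 24, 24, 24))
    calls = []
    for e, n_fil in enumerate(n_per_exp):
        for _ in range(n_fil):
            attached_is_plus = rng.random() < p_plus
            plus_seg = cosmos.EndSegment("dim", float(rng.uniform(3, 8)))
            minus_seg = cosmos.EndSegment("bright", float(rng.uniform(1, 3)))
            att, far = (plus_seg, minus_seg) if attached_is_plus else (minus_seg, plus_seg)
            profile = cosmos.FilamentProfile(att, far, "a")
            calls.append({"experiment": e, "call": cosmos.classify_capture_polarity(profile)})
    capture = cosmos.summarize_capture(pd.DataFrame(calls))

    return {
        "coloc_mean_pct": 100 * coloc.mean_fraction,
        "coloc_sem_pct": 100 * coloc.sem_fraction,
        "negative_control_pct": 100 * negative.mean_fraction,
        "chance_coloc_pct": 100 * float(coloc.per_fov.chance_fraction.mean()),
        "registration_rms_px": regmap.residual_rms,
        "capture_mean_pct_plus": capture["mean_pct_plus"],
        "capture_sd_pct_plus": capture["sd_pct_plus"],
        "capture_pooled_pct_plus": capture["pooled_pct_plus"],
        "capture_n_total": capture["n_total"],
        "n_reference_sites": int(coloc.per_fov.n_reference.sum()),
    }


# ---------------------------------------------------------------------------
# Photobleach copy counting
# ---------------------------------------------------------------------------


def stage_bleach(seed: int, params: dict, outdir: Path, log) -> dict:
    """Bleach-trace simulation -> step detection -> copy-number histogram.

    Defaults emulate the Cse4-like photobleach data set: 591 traces with
    1-4 copies, SNR 5, 0.5 s frames.
    """
    n_traces = params.get("n_traces", 591)
    copy_probs = params.get("copy_probs", (0.35, 0.35, 0.2, 0.1))  # 1..4 copies
    snr = params.get("snr", 5.0)
    step_height = 100.0
    rng = np.random.default_rng(_child_seed(seed, "bleach"))

    fits, truths = [], []
    for i in range(n_traces):
        n = int(rng.choice(np.arange(1, 1 + len(copy_probs)), p=copy_probs))
        cfg = simgen.BleachTraceConfig(
            n_fluors=n, step_height=step_height, noise_sd=step_height / snr,
            n_frames=200, seed=_child_seed(seed, f"bleach-{i}"),
        )
        trace, truth = simgen.make_bleach_trace(cfg)
        fits.append(bleachsteps.detect_steps(trace))
        truths.append(truth.values["n_steps"])
    hist = bleachsteps.copy_number_histogram(fits)
    detected = np.array([f.n_down_steps for f in fits])
    truths = np.array(truths)
    pd.DataFrame({"copies": list(hist), "count": list(hist.values())}).to_csv(
        outdir / "copy_number_histogram.csv", index=False
    )
    return {
        "n_traces": n_traces,
        "histogram": {int(k): int(v) for k, v in hist.items()},
        "histogram_total": int(sum(hist.values())),
        "exact_recovery_fraction": float(np.mean(detected == truths)),
        "step_recovery_fraction": float(
            np.minimum(detected, truths).sum() / truths.sum()
        ),
    }


# ---------------------------------------------------------------------------
# Flip-flop nanometry
# ---------------------------------------------------------------------------

# component -> (nominal displacement nm, total intervals, n assemblies)
END_ATTACHED_DESIGN = {
    "CEN_DNA": (16.0, 74, 13),
    "Cse4": (12.0, 67, 9),
    "Ndc80": (37.0, 116, 19),
    "Dam1": (65.0, 128, 22),
}
ASSEMBLY_SD_NM = 8.0  # assembly-to-assembly spread of the true displacement
LOC_NOISE_NM = 10.0


def _simulate_component(
    seed: int,
    tag: str,
    d_plus: float,
    d_minus: float,
    n_assemblies: int,
    n_intervals_total: int,
    assembly_sd: float = ASSEMBLY_SD_NM,
    tether_from_dna: bool = False,
    min_frames: int = 10,
) -> pd.DataFrame:
    """Simulate assemblies of one tagged component; pool displacements.

    Each assembly's true displacement is drawn around the nominal value
    (assembly-to-assembly spread ``assembly_sd``); its trajectory is
    generated, segmented on the flow schedule, and reduced to per
    interval displacements from the inferred tether. With
    ``tether_from_dna`` the tether comes from a co-simulated symmetric
    DNA-marker trajectory sharing the same anchor, as required when
    opposite-direction displacements differ.
    """
    rng = np.random.default_rng(_child_seed(seed, tag))
    per_assembly = max(2, int(np.ceil(n_intervals_total / n_assemblies)))
    n_cycles = max(1, (per_assembly + 1) // 2)
    frames = []
    for a in range(n_assemblies):
        dp = max(float(rng.normal(d_plus, assembly_sd)), 0.5)
        dm = max(float(rng.normal(d_minus, assembly_sd)), 0.5)
        tether = tuple(rng.uniform(200, 800, size=2))
        cfg = simgen.FlipFlopConfig(
            tether_xy=tether,
            displacement_by_direction=((TOWARD_PLUS, dp), (TOWARD_MINUS, dm)),
            loc_noise_sd=LOC_NOISE_NM,
            n_cycles=n_cycles,
            seed=_child_seed(seed, f"{tag}-a{a}"),
        )
        traj, schedule, _ = simgen.make_flipflop_trajectory(cfg)
        intervals = flipflop.segment_intervals(traj, schedule, min_frames=min_frames)
        if tether_from_dna:
            dna_cfg = simgen.FlipFlopConfig(
                tether_xy=tether,
                displacement_by_direction=((TOWARD_PLUS, 16.0), (TOWARD_MINUS, 16.0)),
                loc_noise_sd=LOC_NOISE_NM,
                n_cycles=n_cycles,
                seed=_child_seed(seed, f"{tag}-dna{a}"),
            )
            dna_traj, dna_sched, _ = simgen.make_flipflop_trajectory(dna_cfg)
            dna_intervals = flipflop.segment_intervals(dna_traj, dna_sched, min_frames=min_frames)
            tether_hat, _ = flipflop.infer_tether_and_displacements(
                dna_intervals, dna_sched.flow_axis
            )
            disp = flipflop.displacements_from_tether(
                intervals, tether_hat, schedule.flow_axis, component=tag,
                geometry="side",
            )
        else:
            _, disp = flipflop.infer_tether_and_displacements(
                intervals, schedule.flow_axis, component=tag
            )
        disp = disp.assign(assembly=a)
        frames.append(disp)
    pooled = pd.concat(frames, ignore_index=True)
    if len(pooled) > n_intervals_total:
        pooled = pooled.iloc[:n_intervals_total].reset_index(drop=True)
    return pooled


def stage_flipflop(seed: int, params: dict, outdir: Path, log) -> dict:
    """Nanometry chains for end-attached and side-attached assemblies.

    End-attached: four tagged components at their published interval
    counts, each fit with a single Gaussian; intra-kinetochore
    separations follow by subtraction of the fitted means. Side-attached
    (polarity-marked): asymmetric displacements 39 nm toward plus /
    14 nm toward minus, tether located from the co-tracked DNA marker;
    reports per-direction medians and the two-Gaussian mixture fit of
    the pooled (direction-blind) distribution.
    """
    metrics: dict = {}
    fitted_means = {}
    all_sets = {}
    for comp, (d, n_int, n_asm) in END_ATTACHED_DESIGN.items():
        disp = _simulate_component(seed, f"ff-{comp}", d, d, n_asm, n_int)
        fit = flipflop.fit_displacement_model(
            disp.displacement_nm.to_numpy(), k=1, seed=_child_seed(seed, f"fit-{comp}")
        )
        fitted_means[comp] = fit.means[0]
        all_sets[comp] = disp
        metrics[f"{comp}_mean_nm"] = fit.means[0]
        metrics[f"{comp}_sem_nm"] = fit.sem_means[0]
        metrics[f"{comp}_n_intervals"] = int(len(disp))
    pd.concat(all_sets.values(), ignore_index=True).to_csv(
        outdir / "end_attached_displacements.csv", index=False
    )

    metrics["ndc80_minus_cse4_nm"] = fitted_means["Ndc80"] - fitted_means["Cse4"]
    metrics["dam1_minus_ndc80_nm"] = fitted_means["Dam1"] - fitted_means["Ndc80"]

    # side-attached, polarity-marked (asymmetric 39 / 14 nm)
    side = _simulate_component(
        seed, "ff-side", 39.0, 14.0, 11, 75, assembly_sd=6.0, tether_from_dna=True
    )
    side.to_csv(outdir / "side_attached_displacements.csv", index=False)
    plus = side[side.direction == TOWARD_PLUS].displacement_nm.to_numpy()
    minus = side[side.direction == TOWARD_MINUS].displacement_nm.to_numpy()
    metrics["side_plus_median_nm"] = float(np.median(plus))
    metrics["side_minus_median_nm"] = float(np.median(minus))
    metrics["side_plus_mean_nm"] = float(np.mean(plus))
    metrics["side_minus_mean_nm"] = float(np.mean(minus))
    ks = ks_two_sample(plus, minus)
    metrics["side_direction_ks_p"] = ks.pvalue

    # direction-blind pooled distribution: two-component mixture expected
    mix = flipflop.fit_displacement_model(
        side.displacement_nm.to_numpy(), seed=_child_seed(seed, "fit-side")
    )
    metrics["side_mixture_k"] = mix.k
    metrics["side_mixture_means_nm"] = list(mix.means)
    metrics["side_mixture_weights"] = list(mix.weights)
    return metrics


# ---------------------------------------------------------------------------
# Trap mechanics
# ---------------------------------------------------------------------------


def stage_trap(seed: int, params: dict, outdir: Path, log) -> dict:
    """Sliding friction and rupture-strength chains.

    Sliding: 24 bead-microtubule pairs pulled alternately at 1 pN;
    per-pair drag drawn around gamma_plus = 1/109, gamma_minus = 1/674
    pN*s/nm so speeds emulate the published 109 vs 674 nm/s asymmetry.
    Rupture: 43 plus-end and 26 minus-end force ramps at 0.25 pN/s with
    the 23 pN trap load limit, strengths gamma-distributed around means
    9.7 and 3.3 pN.
    """
    rng = np.random.default_rng(_child_seed(seed, "trap"))
    n_pairs = params.get("n_pairs", 24)
    gamma_plus0 = params.get("gamma_plus", 1.0 / 109.0)
    gamma_minus0 = params.get("gamma_minus", 1.0 / 674.0)
    pair_sd = params.get("pair_log_sd", 0.35)

    events = []
    for p in range(n_pairs):
        gp = gamma_plus0 * float(rng.lognormal(0.0, pair_sd))
        gm = gamma_minus0 * float(rng.lognormal(0.0, pair_sd))
        cfg = simgen.SlidingConfig(
            gamma_plus=gp, gamma_minus=gm,
            force_schedule=((9.0, 1.0), (2.0, -1.0)) * 3,
            seed=_child_seed(seed, f"slide-{p}"),
        )
        record, _ = simgen.make_sliding_record(cfg)
        for epoch in trapmech.segment_force_epochs(record):
            events.append(trapmech.event_speed(epoch, pair_id=f"pair{p}"))
    friction = trapmech.friction_coefficient(events)
    friction["events"].to_csv(outdir / "sliding_events.csv", index=False)
    pooled = friction["pooled"]
    sp = pooled.loc[TOWARD_PLUS]
    sm = pooled.loc[TOWARD_MINUS]
    ks_speed = ks_two_sample(
        friction["events"].query("direction == @TOWARD_PLUS").speed_nm_s,
        friction["events"].query("direction == @TOWARD_MINUS").speed_nm_s,
    )

    # rupture ramps; strength draws are conditioned on surviving the
    # preload, as in the experiment (preload failures were not ramped)
    preload = params.get("preload_pN", 1.0)

    def run_ruptures(mean_pN, sd_pN, n, end, tag):
        shape = (mean_pN / sd_pN) ** 2
        scale = sd_pN**2 / mean_pN
        draw_rng = np.random.default_rng(_child_seed(seed, f"{tag}-draws"))
        evs, truths = [], []
        n_preload_failures = 0
        for i in range(n):
            s = float(draw_rng.gamma(shape, scale))
            while s <= preload + 0.4:  # indistinguishable from preload failure
                n_preload_failures += 1
                s = float(draw_rng.gamma(shape, scale))
            cfg = simgen.RuptureConfig(
                preload_pN=preload,
                strength_distribution=("gamma", shape, scale),
                seed=_child_seed(seed, f"{tag}-{i}"),
            )
            record, truth = simgen.make_rupture_record(cfg, strength=s)
            evs.append(
                trapmech.detect_rupture(record, end=end, bead_id=f"{tag}{i}")
            )
            truths.append(truth.values)
        return evs, truths, n_preload_failures

    plus_ev, plus_truth, _ = run_ruptures(9.7, 6.6, 43, "plus", "rup-plus")
    minus_ev, minus_truth, _ = run_ruptures(3.3, 2.5, 26, "minus", "rup-minus")
    s_plus = trapmech.summarize_strengths(plus_ev)
    s_minus = trapmech.summarize_strengths(minus_ev)
    ks_rup = ks_two_sample(
        [e.peak_force_pN for e in plus_ev if not e.censored],
        [e.peak_force_pN for e in minus_ev if not e.censored],
    )
    pd.DataFrame(
        [{"end": e.end, "peak_force_pN": e.peak_force_pN, "censored": e.censored}
         for e in plus_ev + minus_ev]
    ).to_csv(outdir / "rupture_events.csv", index=False)

    return {
        "speed_plus_nm_s": float(sp.speed_mean),
        "speed_plus_sem": float(sp.speed_sem),
        "speed_minus_nm_s": float(sm.speed_mean),
        "speed_minus_sem": float(sm.speed_sem),
        "speed_fold_asymmetry": float(sm.speed_mean / sp.speed_mean),
        "gamma_plus": float(sp.gamma_mean),
        "gamma_minus": float(sm.gamma_mean),
        "gamma_fold_asymmetry": float(sp.gamma_mean / sm.gamma_mean),
        "speed_ks_p": ks_speed.pvalue,
        "n_sliding_events": int(len(friction["events"])),
        "rupture_plus_mean_pN": s_plus["mean_pN"],
        "rupture_plus_sem_pN": s_plus["sem_pN"],
        "rupture_plus_n": s_plus["n_uncensored"],
        "rupture_plus_censored": s_plus["n_censored"],
        "rupture_minus_mean_pN": s_minus["mean_pN"],
        "rupture_minus_sem_pN": s_minus["sem_pN"],
        "rupture_minus_n": s_minus["n_uncensored"],
        "rupture_fold_asymmetry": s_plus["mean_pN"] / s_minus["mean_pN"],
        "rupture_ks_p": ks_rup.pvalue,
    }
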