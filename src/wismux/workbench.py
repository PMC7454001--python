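"""Experiment orchestration: configuration, end-to-end runs, verification.

An experiment is: build a synthetic scene -> acquire it through the
multiplexer -> demultiplex -> raw/spike filtering and event analysis ->
PSD de-embedding against a grounded-input acquisition -> summary tables.
Everything is seeded and the provenance record (config hash, seed, library
versions) is sufficient to reproduce any table bit for bit.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import reference_data as ref
from .electrode import (ElectrodeState, ImpedanceSpectrum, implanted_interface,
                        pbs_interface)
from .mux import (MuxConfig, build_sequence, demultiplex, save_streams,
                  simulate_acquisition)
from .noise import compare_noise, de_embed, estimate_psd, integrate_band
from .scenes import LfpConfig, Scene, SpikeSceneConfig, render_scene
from .spikes import (detect_crossings, hoop_isolate, mean_waveform_snr,
                     noise_floor, raw_filter, spike_filter, summarize_channels)
from .wis import (WisParams, neb_ratio, neb_wis, neb_wis_quadrature,
                  predict_baseband_noise)

__all__ = ["ExperimentConfig", "ExperimentResult", "run_experiment",
           "run_verification_suite"]

_INTERFACES = {"pbs": pbs_interface, "implanted": implanted_interface}


def _build_electrode(spec: dict) -> ElectrodeState:
    kind = spec.get("interface", "implanted")
    if isinstance(kind, str):
        if "impedance_file" in spec:
            imp = ImpedanceSpectrum.from_table(spec["impedance_file"])
        else:
            imp = _INTERFACES[kind]().spectrum()
    else:
        from .electrode import InterfaceModel
        imp = InterfaceModel(kind["r_series_ohm"], kind["r_parallel_ohm"],
                             kind["c_parallel_f"]).spectrum()
    return ElectrodeState(
        electrode_id=int(spec["id"]), impedance=imp,
        v_offset=float(spec.get("offset_mv", 0.0)) * 1e-3,
        drift_rate=float(spec.get("drift_uv_per_s", 300.0)) * 1e-6,
        temperature=float(spec.get("temperature_k", 310.0)))


@dataclass
class ExperimentConfig:
    """Validated experiment description (see ``default()`` for the shape)."""

    raw: dict
    electrodes: list
    lfp: LfpConfig | None
    spikes: SpikeSceneConfig | None
    mux: MuxConfig
    wis: WisParams
    seed: int = 1
    duration_s: float = 1.0
    f_sim: float = 6e6
    analysis: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        mux_d = dict(d.get("mux", {}))
        allocation = {int(k): int(v) for k, v in mux_d.pop("allocation").items()}
        scheme = mux_d.pop("scheme", "contiguous")
        n_tot = int(mux_d.pop("n_tot", 20))
        f_mux = float(mux_d.pop("f_mux", 600e3))
        if "f_s" in mux_d:
            f_s = float(mux_d.pop("f_s"))
            if abs(f_s * n_tot - f_mux) > 1e-6 * f_mux:
                raise ValueError(
                    f"inconsistent rates: f_s*n_tot={f_s * n_tot} != f_mux={f_mux}")
        seq = build_sequence(allocation, n_tot, scheme=scheme,
                             seed=int(d.get("seed", 1)))
        mux = MuxConfig(f_mux=f_mux, n_tot=n_tot, slice_sequence=seq, **mux_d)
        wis = WisParams.from_mux(mux.f_mux, mux.settle_fraction)
        electrodes = [_build_electrode(e) for e in d["electrodes"]]
        ids = [e.electrode_id for e in electrodes]
        if sorted(ids) != sorted(allocation):
            raise ValueError("allocation electrode ids must match electrode list")
        scene_d = d.get("scene", {})
        lfp = LfpConfig(**scene_d["lfp"]) if scene_d.get("lfp") is not None else None
        spikes = (SpikeSceneConfig(**scene_d["spikes"])
                  if scene_d.get("spikes") is not None else None)
        return cls(raw=d, electrodes=electrodes, lfp=lfp, spikes=spikes,
                   mux=mux, wis=wis, seed=int(d.get("seed", 1)),
                   duration_s=float(d.get("duration_s", 1.0)),
                   f_sim=float(d.get("f_sim", 6e6)),
                   analysis=dict(d.get("analysis", {})))

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def default(cls, n_electrodes: int = 4, n_ave: int = 2,
                duration_s: float = 1.0, seed: int = 1,
                f_sim: float = 6e6) -> "ExperimentConfig":
        """In-vivo-like operating point: implanted interfaces, LFP + bursting
        spikes, 600 kHz / 20 slots, the measured offset magnitudes."""
        offsets = [r[-1] for r in ref.spike_comparison_table().itertuples(index=False)]
        d = {
            "seed": seed, "duration_s": duration_s, "f_sim": f_sim,
            "electrodes": [{"id": i + 1, "offset_mv": offsets[i % len(offsets)],
                            "interface": "implanted", "temperature_k": 310.0}
                           for i in range(n_electrodes)],
            "scene": {"lfp": {}, "spikes": {}},
            "mux": {"allocation": {i + 1: n_ave for i in range(n_electrodes)}},
            "analysis": {},
        }
        return cls.from_dict(d)

    def config_hash(self) -> str:
        blob = json.dumps(self.raw, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class ExperimentResult:
    scene: Scene
    streams: list
    raw_streams: list
    spike_streams: list
    snippets: dict
    reports: dict
    summary: pd.DataFrame
    noise_table: pd.DataFrame
    provenance: dict


def run_experiment(cfg: ExperimentConfig, outdir=None) -> ExperimentResult:
    """Scene -> acquisition -> demux -> spike pipeline -> noise tables."""
    an = cfg.analysis
    k_thr = float(an.get("threshold_sigma", 3.0))
    k_hoop = float(an.get("hoop_sigma", 1.7))
    snippet_s = float(an.get("snippet_ms", 1.6)) * 1e-3
    band = tuple(an.get("noise_band_hz", (500.0, 5000.0)))

    scene = render_scene(cfg.electrodes, cfg.lfp, cfg.spikes, cfg.duration_s,
                         f_sim=cfg.f_sim, seed=cfg.seed)
    raw = simulate_acquisition(scene, cfg.mux, cfg.wis, seed=cfg.seed + 1)
    streams = demultiplex(raw, cfg.mux)

    grounded_scene = Scene(
        f_sim=cfg.f_sim, duration_s=cfg.duration_s, electrodes=cfg.electrodes,
        signals=[np.zeros(int(round(cfg.duration_s * cfg.f_sim)))] * len(cfg.electrodes))
    grounded = demultiplex(
        simulate_acquisition(grounded_scene, cfg.mux, cfg.wis,
                             seed=cfg.seed + 2, calibrate=False))

    raw_streams = [raw_filter(s) for s in streams]
    spike_streams = [spike_filter(s) for s in streams]

    snippets, reports, floors, offsets = {}, {}, {}, {}
    for s in spike_streams:
        snips = detect_crossings(s, k=k_thr, snippet_s=snippet_s)
        if snips.n_events >= 2:
            template = snips.waveforms.mean(axis=0)
            snips = hoop_isolate(snips, template, k=k_hoop)
        snippets[s.electrode_id] = snips
        if snips.n_events:
            reports[s.electrode_id] = mean_waveform_snr(snips)
        floors[s.electrode_id] = noise_floor(s, snips)
    for e in cfg.electrodes:
        offsets[e.electrode_id] = e.v_offset
    summary = summarize_channels(reports, floors, offsets)

    measured, predicted = {}, {}
    segment_s = min(0.25, cfg.duration_s / 4)
    for s, g, e in zip(streams, grounded, cfg.electrodes):
        psd_m = estimate_psd(s, segment_s=segment_s)
        psd_g = estimate_psd(g, segment_s=segment_s)
        measured[s.electrode_id] = integrate_band(de_embed(psd_m, psd_g), *band)
        predicted[s.electrode_id] = predict_baseband_noise(
            e.impedance, cfg.wis, cfg.mux.f_s, s.n_ave, band=band,
            temperature=e.temperature)
    noise_table = compare_noise(measured, predicted)

    provenance = {
        "config_hash": cfg.config_hash(), "seed": cfg.seed,
        "numpy": np.__version__,
        "scipy": __import__("scipy").__version__,
        "n_frames": streams[0].samples.size if streams else 0,
    }

    result = ExperimentResult(scene=scene, streams=streams,
                              raw_streams=raw_streams,
                              spike_streams=spike_streams, snippets=snippets,
                              reports=reports, summary=summary,
                              noise_table=noise_table, provenance=provenance)
    if outdir is not None:
        _write_result(result, cfg, outdir)
    return result


def _write_result(result: ExperimentResult, cfg: ExperimentConfig, outdir):
    import pathlib
    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    save_streams(out / "channels.npz", result.streams,
                 header={"config_hash": cfg.config_hash()})
    result.summary.to_csv(out / "spike_summary.csv", index=False)
    result.noise_table.to_csv(out / "noise_comparison.csv", index=False)
    result.scene.write_truth(out / "truth.txt")
    with open(out / "provenance.json", "w") as fh:
        json.dump(result.provenance, fh, indent=2, sort_keys=True)


def _snr_from_table(pkpk_uv: float, sd_uv: float) -> float:
    """Worked-example SNR from printed pk-pk and SD_eps values, computed by
    running the mean-waveform statistic on a constructed snippet pair."""
    from .spikes import SnippetSet
    from .scenes import default_template
    _, w = default_template(f_grid=30e3)
    wbar = w * pkpk_uv * 1e-6  # unit-pkpk template scaled to the printed pkpk
    d = np.full_like(wbar, sd_uv * 1e-6)
    snips = SnippetSet(0, np.array([0.0, 0.1]), np.vstack([wbar + d, wbar - d]),
                       30e3, -1.0, 1.0, 16)
    return mean_waveform_snr(snips).snr


def run_verification_suite(include_simulation: bool = False, seed: int = 1) -> dict:
    """Recompute the analytic identities and worked examples; report verdicts.

    Returns {check_name: {"value", "expected", "tol", "pass"}}.  With
    ``include_simulation`` a reduced-size end-to-end noise check is added.
    """
    wis = WisParams()
    checks = {}

    def add(name, value, expected, tol):
        checks[name] = {"value": value, "expected": expected, "tol": tol,
                        "pass": bool(abs(value - expected) <= tol)}

    add("neb_khz", round(neb_wis(wis.t_int) / 1e3), 333, 0)
    add("neb_quadrature_khz", neb_wis_quadrature(wis.t_int) / 1e3, 333.333, 0.4)
    add("settling_neb_ratio_2sf", float(round(neb_ratio(1e-3), 1)), 3.5, 0)
    add("n_tot", round(600e3 / 30e3), 20, 0)
    add("slot_us", round(1e6 / 600e3, 2), 1.67, 0)
    t3 = ref.slice_allocation_table()
    for (e, s), expect in (((3, 2), 2.61), ((4, 2), 2.68), ((3, 5), 2.88)):
        row = t3[(t3.electrode == e) & (t3.slices == s)].iloc[0]
        add(f"snr_e{e}_{s}slices",
            round(_snr_from_table(row.pkpk_uv, row.sd_eps_uv), 2), expect, 0)
    t2 = ref.spike_comparison_table()
    add("bench_snr_mean", round(float(t2.bench_snr.mean()), 2), 3.07, 0)
    add("chip_pkpk_mean_uv", round(float(t2.chip_pkpk_uv.mean()), 2), 15.62, 0)
    t5 = ref.noise_comparison_in_vivo()
    add("in_vivo_de_embedded_mean_uvrms",
        round(float(t5.de_embedded_uvrms.mean()), 2), 4.77, 0)

    if include_simulation:
        from .electrode import ImpedanceSpectrum
        imp = ImpedanceSpectrum.from_resistance(5e3)
        cfg = ExperimentConfig.default(n_electrodes=1, n_ave=1,
                                       duration_s=1.0, seed=seed)
        pred = predict_baseband_noise(imp, cfg.wis, cfg.mux.f_s, 1,
                                      temperature=295.0)
        meas = _simulated_band_noise(imp, cfg, seed)
        add("end_to_end_noise_ratio", meas / pred, 1.0, 0.10)
    return checks


def _simulated_band_noise(imp, cfg: ExperimentConfig, seed: int,
                          duration: float = 1.0) -> float:
    """De-embedded 500 Hz-5 kHz rms of a simulated noise-only acquisition."""
    e = ElectrodeState(1, imp, v_offset=0.0, drift_rate=0.0, temperature=295.0)
    mux = MuxConfig(slice_sequence=build_sequence({1: 1}, 20))
    scene = render_scene([e], None, None, duration, f_sim=12e6, seed=seed)
    s = demultiplex(simulate_acquisition(scene, mux, seed=seed + 1))[0]
    zeros = Scene(f_sim=scene.f_sim, duration_s=duration, electrodes=[e],
                  signals=[np.zeros_like(scene.signals[0])])
    g = demultiplex(simulate_acquisition(zeros, mux, seed=seed + 2,
                                         calibrate=False))[0]
    psd = de_embed(estimate_psd(s), estimate_psd(g))
    return integrate_band(psd)
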