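"""End-to-end orchestration: configuration, standard-format IO, the pipeline
runner and the reproducibility manifest.

Stage order mirrors the analysis chain: semantic-distance scoring and
inclusion filtering, wavelet spectra and aperiodic fits, burst detection
with individual-alpha-frequency selection, phase-slope-index connectivity,
and the cluster permutation contrast.  Every run writes a manifest with the
configuration, the seed and a content hash of each output so identical runs
are byte-identical.

Units are microvolts, seconds and hertz throughout.  Epoched EEG travels as
a NumPy ``.npz`` archive (one array per participant and condition, shape
(n_epochs, n_channels, n_samples)) plus a JSON sidecar carrying fs, channel
names and condition labels; EDF and BrainVision continuous recordings can be
ingested through mne given a sidecar with epoch onsets.  Artefact masks are
computed at load time with the +/-80 microvolt rule when absent.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bursts as _bursts
from . import clusterperm as _clusterperm
from . import psi as _psi
from . import semdist as _semdist
from . import spectral as _spectral
from .synthgen import GroupDataset

logger = logging.getLogger("oscflux.pipeline")

ARTEFACT_THRESHOLD_UV = 80.0


@dataclass
class RunConfig:
    """All pipeline parameters; defaults follow the study protocol
    (3-cycle wavelets, 95th-percentile threshold, 0.1 s padding, +/-80 uV
    artefact rule, 1 s minimum thinking time, 20% artefact maximum, 10/5
    response minima, 5000 permutations at two-tailed .05)."""

    epochs_path: str = ""
    responses_path: str = ""
    vectors_path: str = ""
    output_dir: str = "results"
    # spectral
    freq_min: float = 4.0
    freq_max: float = 40.0
    freq_step: float = 0.5
    n_cycles: float = 3.0
    pad_seconds: float = 0.1
    aperiodic_mode: str = "knee"
    # detection
    percentile: float = 0.95
    min_cycles: float = 3.0
    alpha_band: tuple[float, float] = (8.0, 13.0)
    # psi
    segment_length: float = 1.0
    overlap: float = 0.5
    psi_band: tuple[float, float] = (8.0, 13.0)
    # cluster
    n_perm: int = 5000
    alpha: float = 0.05
    scc_mode: str = "strong"
    # semdist
    distance_mode: str = "consecutive"
    # misc
    seed: int = 0

    def freqs(self) -> np.ndarray:
        return _spectral.freq_grid(self.freq_min, self.freq_max, self.freq_step)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["alpha_band"] = list(d["alpha_band"])
        d["psi_band"] = list(d["psi_band"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        for key in ("alpha_band", "psi_band"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class EpochedRecording:
    """Epochs of one participant in one condition (epochs x channels x samples)."""

    data: np.ndarray
    fs: float
    channels: list[str]
    condition: str
    participant: str
    artefact_mask: np.ndarray = field(default=None)  # bool, same shape as data

    def __post_init__(self):
        if self.artefact_mask is None:
            self.artefact_mask = np.abs(self.data) > ARTEFACT_THRESHOLD_UV

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def save_epochs(dataset: GroupDataset, path_stem) -> None:
    """Write a group dataset as <stem>.npz + <stem>.json sidecar."""
    stem = Path(path_stem)
    arrays = {}
    participants = dataset.participants
    conditions = sorted(next(iter(dataset.data.values())).keys())
    for pid in participants:
        for cond in conditions:
            arrays[f"{pid}__{cond}"] = dataset.data[pid][cond]
    np.savez(stem.with_suffix(".npz"), **arrays)
    sidecar = {
        "fs": dataset.fs,
        "channel_names": dataset.channels,
        "participants": participants,
        "conditions": conditions,
        "couplings": [
            {"driver": c.driver, "receiver": c.receiver, "lag": c.lag,
             "band": list(c.band), "coupling_gain": c.coupling_gain}
            for c in dataset.couplings],
    }
    stem.with_suffix(".json").write_text(json.dumps(sidecar, indent=1, sort_keys=True))


def load_epochs(path, fmt: str | None = None) -> list[EpochedRecording]:
    """Read epoched EEG as a list of EpochedRecording.

    Formats: ``npz`` (matrix + JSON sidecar, the package's native format) or
    ``edf`` / ``brainvision`` continuous recordings read through mne and cut
    into epochs using a JSON sidecar with ``epoch_onsets`` (seconds),
    ``epoch_durations`` and ``conditions``.  Artefact masks are computed with
    the +/-80 uV rule.
    """
    path = Path(path)
    if fmt is None:
        fmt = {".npz": "npz", ".edf": "edf", ".vhdr": "brainvision"}.get(
            path.suffix.lower())
    if fmt is None:
        raise ValueError(f"cannot infer format of {path.name}")
    if fmt == "npz":
        sidecar_path = path.with_suffix(".json")
        if not sidecar_path.exists():
            raise FileNotFoundError(f"missing sidecar {sidecar_path.name}")
        side = json.loads(sidecar_path.read_text())
        with np.load(path) as npz:
            if len(npz.files) == 0:
                raise ValueError(f"{path.name} contains no epochs")
            out = []
            for pid in side["participants"]:
                for cond in side["conditions"]:
                    key = f"{pid}__{cond}"
                    out.append(EpochedRecording(
                        data=npz[key], fs=float(side["fs"]),
                        channels=list(side["channel_names"]),
                        condition=cond, participant=pid))
        return out
    if fmt in ("edf", "brainvision"):
        import mne
        reader = mne.io.read_raw_edf if fmt == "edf" else mne.io.read_raw_brainvision
        raw = reader(path, preload=True, verbose="error")
        side = json.loads(path.with_suffix(".json").read_text())
        fs = float(raw.info["sfreq"])
        data = raw.get_data() * 1e6  # volts -> microvolts
        out = []
        for k, (onset, dur, cond) in enumerate(zip(
                side["epoch_onsets"], side["epoch_durations"], side["conditions"])):
            i0 = int(round(onset * fs))
            i1 = i0 + int(round(dur * fs))
            out.append(EpochedRecording(
                data=data[np.newaxis, :, i0:i1], fs=fs,
                channels=list(raw.ch_names), condition=cond,
                participant=side.get("participant", path.stem)))
        return out
    raise ValueError(f"unknown format {fmt!r}")


def write_vectors(vectors: dict, path) -> None:
    """GloVe-style whitespace-delimited word-vector table."""
    with open(path, "w") as fh:
        for word, vec in vectors.items():
            fh.write(word + " " + " ".join(f"{x:.6f}" for x in vec) + "\n")


def read_vectors(path) -> dict:
    vectors = {}
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) < 3:
                continue
            vectors[parts[0]] = np.asarray(parts[1:], dtype=float)
    if not vectors:
        raise ValueError(f"no vectors found in {path}")
    return vectors


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def run_semdist_stage(config: RunConfig, outdir: Path) -> dict:
    responses = pd.read_csv(config.responses_path)
    vectors = read_vectors(config.vectors_path)
    scored = _semdist.score_table(responses, vectors, mode=config.distance_mode)
    scored = _semdist.split_table(scored)
    kept, report = _semdist.apply_inclusion_filters(scored)
    kept.to_csv(outdir / "scored_responses.csv", index=False)
    (outdir / "exclusions.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report


def run_burst_stage(config: RunConfig, recordings: list[EpochedRecording],
                    outdir: Path) -> pd.DataFrame:
    """Wavelet spectra, aperiodic fits, burst detection, IAF, alpha measures."""
    freqs = config.freqs()
    rows = []
    event_rows = []
    by_participant: dict[str, list[EpochedRecording]] = {}
    for rec in recordings:
        by_participant.setdefault(rec.participant, []).append(rec)
    for pid, recs in by_participant.items():
        channels = recs[0].channels
        for ci, ch in enumerate(channels):
            tfrs = []
            keys = []
            for rec in recs:
                for ei in range(rec.n_epochs):
                    tfr = _spectral.morlet_tfr(
                        rec.data[ei, ci], rec.fs, freqs,
                        n_cycles=config.n_cycles, pad_seconds=config.pad_seconds,
                        artefact_mask=rec.artefact_mask[ei, ci])
                    tfrs.append(tfr)
                    keys.append((rec.condition, ei))
            spectrum = _spectral.mean_log_spectrum(tfrs)
            fit = _spectral.fit_aperiodic(spectrum, freqs, mode=config.aperiodic_mode)
            thr = _spectral.detection_threshold(
                fit, freqs, percentile=config.percentile, min_cycles=config.min_cycles)
            all_events = []
            for tfr, (cond, ei) in zip(tfrs, keys):
                evs = _bursts.detect_bursts(tfr, thr, channel=ch, epoch=ei)
                all_events.append((cond, ei, tfr, evs))
            iaf = _bursts.find_iaf(
                [e for (_, _, _, evs) in all_events for e in evs],
                alpha_band=tuple(config.alpha_band))
            for cond, ei, tfr, evs in all_events:
                fi = int(np.argmin(np.abs(freqs - iaf))) if np.isfinite(iaf) else -1
                iaf_events = [e for e in evs if np.isfinite(iaf) and e.freq == freqs[fi]]
                valid_dur = (tfr.valid[fi].sum() / tfr.fs) if fi >= 0 else \
                    tfr.valid.any(axis=0).sum() / tfr.fs
                if valid_dur <= 0:
                    continue
                m = _bursts.epoch_alpha_measures(iaf_events, valid_dur)
                rows.append({"participant": pid, "channel": ch, "condition": cond,
                             "epoch": ei, "iaf": iaf,
                             "burst_power": m.burst_power,
                             "burst_proportion": m.burst_proportion,
                             "burst_duration": m.burst_duration,
                             "n_bursts": m.n_bursts})
                for e in evs:
                    event_rows.append({"participant": pid, "channel": ch,
                                       "condition": cond, "epoch": ei,
                                       "freq": e.freq, "onset": e.onset,
                                       "offset": e.offset,
                                       "duration_s": e.duration_s,
                                       "mean_power": e.mean_power})
    measures = pd.DataFrame(rows)
    pd.DataFrame(event_rows).to_csv(outdir / "burst_events.csv", index=False)
    measures.to_csv(outdir / "alpha_measures_epochs.csv", index=False)
    if len(measures):
        agg = _bursts.aggregate_condition_measures(measures)
        agg.to_csv(outdir / "alpha_measures.csv", index=False)
    return measures


def run_psi_stage(config: RunConfig, recordings: list[EpochedRecording],
                  outdir: Path) -> dict:
    """Standardised PSI per participant x condition; long-format CSV export."""
    psis: dict[str, dict[str, np.ndarray]] = {}
    rows = []
    for rec in recordings:
        mat = _psi.psi_standardised(
            rec.data, rec.fs, band=tuple(config.psi_band),
            segment_length=config.segment_length, overlap=config.overlap,
            channels=rec.channels)
        psis.setdefault(rec.participant, {})[rec.condition] = mat.psi_std
        for i, a in enumerate(rec.channels):
            for j, b in enumerate(rec.channels):
                if i != j:
                    rows.append({"participant": rec.participant,
                                 "condition": rec.condition, "from": a, "to": b,
                                 "psi_raw": mat.psi_raw[i, j],
                                 "psi_std": mat.psi_std[i, j]})
    pd.DataFrame(rows).to_csv(outdir / "psi_edges.csv", index=False)
    return psis


def run_cluster_stage(config: RunConfig, psis: dict, channels: list[str],
                      conditions: list[str], outdir: Path):
    A = [psis[p][conditions[0]] for p in sorted(psis)]
    B = [psis[p][conditions[1]] for p in sorted(psis)]
    result = _clusterperm.permutation_test(
        A, B, n_perm=config.n_perm, alpha=config.alpha, seed=config.seed,
        scc_mode=config.scc_mode, channels=channels)
    payload = {
        "t_critical": result.t_critical,
        "alpha": result.alpha,
        "n_permutations": result.n_permutations,
        "conditions": conditions,
        "clusters": [
            {"edges": [[channels[u], channels[v]] for (u, v) in c.edges],
             "condition_membership": c.condition_membership,
             "cluster_stat": c.cluster_stat,
             "p_value": c.p_value,
             "significant": c.significant}
            for c in result.clusters],
    }
    (outdir / "clusters.json").write_text(json.dumps(payload, indent=1, sort_keys=True))
    return result


def run_pipeline(config: RunConfig):
    """Execute every stage and write outputs plus a manifest.

    Any stage failure aborts with the stage name in the raised error.
    Returns the output directory path.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "semdist"
    try:
        exclusions = run_semdist_stage(config, outdir)
        stage = "load_epochs"
        recordings = load_epochs(config.epochs_path)
        channels = recordings[0].channels
        conditions = sorted({r.condition for r in recordings})
        stage = "spectral/bursts"
        measures = run_burst_stage(config, recordings, outdir)
        stage = "psi_connectivity"
        psis = run_psi_stage(config, recordings, outdir)
        stage = "clusterperm"
        run_cluster_stage(config, psis, channels, conditions, outdir)
        if len(measures):
            pivot = measures.groupby(["participant", "condition", "channel"])[
                "burst_proportion"].mean().unstack("channel")
            conds = conditions
            common = sorted(set(pivot.loc[(slice(None), conds[0]), :].index
                                .get_level_values(0)) &
                            set(pivot.loc[(slice(None), conds[1]), :].index
                                .get_level_values(0)))
            if len(common) >= 2:
                MA = pivot.loc[(common, conds[0]), channels].to_numpy()
                MB = pivot.loc[(common, conds[1]), channels].to_numpy()
                topo = _clusterperm.contrast_topography(MA, MB, channels)
                pd.DataFrame(topo).to_csv(outdir / "topography.csv", index=False)
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    config.to_yaml(outdir / "config.yaml")
    manifest = {
        "seed": config.seed,
        "config_hash": hashlib.sha256(
            (outdir / "config.yaml").read_bytes()).hexdigest(),
        "exclusions": exclusions,
        "versions": _versions(),
        "outputs": {p.name: _sha256(p) for p in sorted(outdir.iterdir())
                    if p.is_file() and p.name != "manifest.json"},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return outdir


def _versions() -> dict:
    import mne
    import scipy
    return {"numpy": np.__version__, "scipy": scipy.__version__,
            "pandas": pd.__version__, "mne": mne.__version__}


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

def report(results_dir, figures: bool = False) -> dict:
    """Summarise a completed run: cluster table, distance and thinking-time
    distributions, per-channel contrast map.  Re-entrant; optional figures
    are written headless (Agg backend)."""
    results_dir = Path(results_dir)
    summary: dict = {}
    clusters_path = results_dir / "clusters.json"
    if clusters_path.exists():
        clusters = json.loads(clusters_path.read_text())
        summary["significant_clusters"] = [
            c for c in clusters["clusters"] if c["significant"]]
        summary["t_critical"] = clusters["t_critical"]
    scored_path = results_dir / "scored_responses.csv"
    if scored_path.exists():
        scored = pd.read_csv(scored_path)
        summary["distance_mean"] = float(scored["distance"].mean())
        summary["distance_sd"] = float(scored["distance"].std())
        summary["thinking_time_median"] = float(scored["thinking_time"].median())
        summary["n_responses"] = int(len(scored))
    topo_path = results_dir / "topography.csv"
    if topo_path.exists():
        topo = pd.read_csv(topo_path)
        summary["topography_max_abs_t_channel"] = str(
            topo.loc[topo["t"].abs().idxmax(), "channel"])
    (results_dir / "summary.json").write_text(
        json.dumps(summary, indent=1, sort_keys=True))
    if figures:
        _write_figures(results_dir, summary)
    return summary


def _write_figures(results_dir: Path, summary: dict) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    scored_path = results_dir / "scored_responses.csv"
    if scored_path.exists():
        scored = pd.read_csv(scored_path)
        fig, axes = plt.subplots(1, 2, figsize=(8, 3))
        parts = [scored.loc[scored["split"] == lab, "distance"].dropna()
                 for lab in ("lower", "higher")]
        if all(len(p) for p in parts):
            axes[0].violinplot(parts)
            axes[0].set_xticks([1, 2], ["lower", "higher"])
        axes[0].set_ylabel("semantic distance")
        axes[1].hist(scored["thinking_time"], bins=30)
        axes[1].set_xlabel("thinking time (s)")
        fig.tight_layout()
        fig.savefig(results_dir / "behaviour.png", dpi=100)
        plt.close(fig)

    clusters_path = results_dir / "clusters.json"
    if clusters_path.exists():
        import networkx as nx
        clusters = json.loads(clusters_path.read_text())
        g = nx.DiGraph()
        for c in clusters["clusters"]:
            if c["significant"]:
                for (u, v) in c["edges"]:
                    g.add_edge(u, v)
        fig, ax = plt.subplots(figsize=(4, 4))
        if g.number_of_edges():
            nx.draw_networkx(g, ax=ax, node_color="lightsteelblue",
                             arrows=True, font_size=8)
        ax.set_axis_off()
        fig.savefig(results_dir / "cluster_graph.png", dpi=100)
        plt.close(fig)
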