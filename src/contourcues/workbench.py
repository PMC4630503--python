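"""Reproducible end-to-end runs: configuration, stage orchestration, IO checks.

A run is driven by a single :class:`RunConfig` whose top-level seed is
split deterministically into per-stage seeds (numpy SeedSequence), so one
number reproduces a whole run byte for byte. Stages write plain CSV/JSON
artifacts into the run directory and later stages read them back, which
keeps every intermediate inspectable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cues as cues_mod
from . import io as cio
from .figure_ground import convex_choice_rate, mlra
from .geometry import LocalFrame, local_frame, orientation_bin
from .mds import (
    aggregate_dissimilarity,
    nonmetric_mds,
    normalized_error,
    topographic_config,
)
from .stimuli import has_x_junction, render_stimulus, stratified_select
from .synth import ObserverModel, generate_open_curve, simulate_fg, simulate_similarity

log = logging.getLogger("contourcues")

STAGES = ("simulate", "features", "select", "similarity", "fg")


@dataclass
class RunConfig:
    """All knobs of a pipeline run; round-trips through JSON unchanged."""

    seed: int = 0
    out_dir: str = "run"
    stages: tuple = STAGES
    # corpus generation
    n_patches: int = 60
    smoothness: float = 1.0
    # observers
    n_observers: int = 6
    noise_sd: float = 0.3
    similarity_weights: dict = field(
        default_factory=lambda: {"convexity": 1.0, "closure": 1.0, "symmetry": 1.0}
    )
    fg_weights: tuple = (0.490, 0.0, 0.0755, 0.0, 0.0, 0.0, 0.0)
    n_repetitions: int = 4
    n_fg_reps: int = 100
    # analysis
    mds_restarts: int = 10
    n_random: int = 100
    factor_sets: tuple = (("closure", "convexity"), ("symmetry",))
    version: str = "0.1.0"

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        data["stages"] = tuple(data.get("stages", STAGES))
        data["fg_weights"] = tuple(data.get("fg_weights", cls.fg_weights))
        data["factor_sets"] = tuple(tuple(fs) for fs in data.get("factor_sets", ()))
        return cls(**data)


def stage_seeds(seed: int) -> dict:
    """Deterministic per-stage seeds from the top-level seed."""
    children = np.random.SeedSequence(seed).spawn(len(STAGES))
    return {name: int(ss.generate_state(1)[0] % 2**31)
            for name, ss in zip(STAGES, children)}


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"missing upstream output {path.name!r}; run the {stage!r} stage first")
    return path


def run_pipeline(config: RunConfig) -> Path:
    """Execute the requested stages in order; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_json(out / "config.json")
    seeds = stage_seeds(config.seed)
    logging.basicConfig(format="%(asctime)s %(name)s %(message)s")
    log.setLevel(logging.INFO)
    log.info("run start seed=%d stages=%s", config.seed, ",".join(config.stages))

    patches: dict = {}
    frames: dict[str, LocalFrame] = {}

    def load_corpus():
        mdir = _require(out / "patches", "simulate")
        for txt in sorted(mdir.glob("*.txt")):
            pid = txt.stem
            cmap = cio.load_map(txt)
            from .geometry import ContourPatch, _chain_through

            chain = _chain_through(cmap, (34, 34))
            patches[pid] = ContourPatch(cmap.grid, chain=chain, provenance=pid)

    if "simulate" in config.stages:
        rng = np.random.default_rng(seeds["simulate"])
        pdir = out / "patches"
        pdir.mkdir(exist_ok=True)
        made = 0
        attempt = 0
        while made < config.n_patches and attempt < 20 * config.n_patches:
            attempt += 1
            s = int(rng.integers(2**31))
            try:
                patch = generate_open_curve(config.smoothness, seed=s)
                frame = local_frame(patch)
            except ValueError:
                continue
            if has_x_junction(patch):
                continue
            pid = f"p{made:04d}"
            np.savetxt(pdir / f"{pid}.txt", patch.grid, fmt="%d")
            patches[pid] = patch
            frames[pid] = frame
            made += 1
        log.info("simulate: %d patches (%d attempts)", made, attempt)

    if "features" in config.stages:
        if not patches:
            load_corpus()
        records = []
        searches = {}
        for pid, patch in patches.items():
            frame = frames.get(pid) or local_frame(patch)
            frames[pid] = frame
            searches[pid] = cues_mod.optimal_axis(patch)
            records.append({"patch_id": pid, "frame": frame, "patch": patch})
        corpus_max = max(searches[r["patch_id"]].dos_star for r in records)
        rows = []
        for r in records:
            pid, frame, patch = r["patch_id"], r["frame"], r["patch"]
            sr = searches[pid]
            sym = cues_mod.symmetry_index(patch, frame, corpus_max, search=sr)
            rows.append({
                "patch_id": pid,
                "convexity": cues_mod.convexity(frame),
                "closure": cues_mod.closure(patch, frame),
                "symmetry": sym,
                "orientation_deg": frame.tangent_deg,
                "orientation_bin": orientation_bin(frame.tangent_deg),
                "theta_star": sr.theta_star,
                "x_star": sr.x_star,
                "dos_star": sr.dos_star,
                "degenerate_flag": frame.degenerate,
            })
        cio.cue_table_frame(rows).to_csv(out / "cues.csv", index=False)
        log.info("features: corpus_max_dos=%.3f", corpus_max)

    def load_cues() -> pd.DataFrame:
        return pd.read_csv(_require(out / "cues.csv", "features"))

    def cue_vectors(df: pd.DataFrame) -> list:
        return [
            cues_mod.CueVector(
                convexity=row.convexity, closure=int(row.closure),
                symmetry=row.symmetry, orientation_bin=int(row.orientation_bin),
                patch_id=row.patch_id)
            for row in df.itertuples()
        ]

    if "select" in config.stages:
        df = load_cues()
        pool = [(c.patch_id, c) for c in cue_vectors(df)]
        sset = stratified_select(pool, seed=seeds["select"])
        man = pd.DataFrame(
            [(pid, c.convexity, c.closure, c.symmetry, cls.convexity_bin,
              cls.closure_bin, cls.orientation_bin)
             for pid, c, cls in sset.members],
            columns=["patch_id", "convexity", "closure", "symmetry",
                     "convexity_bin", "closure_bin", "orientation_bin"])
        man.to_csv(out / "manifest.csv", index=False)
        if not patches:
            load_corpus()
        sdir = out / "stimuli"
        sdir.mkdir(exist_ok=True)
        for pid, _, _ in sset.members:
            cio.save_stimulus(render_stimulus(patches[pid]), sdir / f"{pid}.png")
        log.info("select: %d of 200 classes filled (seed=%d)", len(sset.members),
                 seeds["select"])

    def selected_cues() -> list:
        man = pd.read_csv(_require(out / "manifest.csv", "select"))
        df = load_cues()
        df = df[df.patch_id.isin(man.patch_id)]
        return cue_vectors(df)

    if "similarity" in config.stages:
        sel = selected_cues()
        rng = np.random.default_rng(seeds["similarity"])
        all_trials = []
        results = {"-".join(sorted(fs)): [] for fs in config.factor_sets}
        for k in range(config.n_observers):
            model = ObserverModel(
                similarity_weights=dict(config.similarity_weights),
                noise_sd=config.noise_sd, seed=int(rng.integers(2**31)),
                observer_id=f"obs{k}")
            trials = simulate_similarity(sel, model, n_repetitions=config.n_repetitions)
            all_trials.append(trials)
            dmat = aggregate_dissimilarity(trials, observer_id=model.observer_id)
            # each factor set is compared to a perceptual configuration of
            # the same dimensionality (1D sets to 1D MDS, 2D to 2D, ...)
            pcfg_by_dims: dict[int, object] = {}
            for fs in config.factor_sets:
                dims = min(len(fs), 3)
                if dims not in pcfg_by_dims:
                    pcfg_by_dims[dims] = nonmetric_mds(
                        dmat, dims=dims, seed=int(rng.integers(2**31)),
                        restarts=config.mds_restarts)
                pcfg = pcfg_by_dims[dims]
                tcfg = topographic_config(sel, fs)
                est = normalized_error(pcfg, tcfg, dmat,
                                       n_random=config.n_random,
                                       seed=int(rng.integers(2**31)),
                                       restarts=config.mds_restarts)
                results["-".join(sorted(fs))].append(
                    {"observer": model.observer_id, "stress": pcfg.stress,
                     "raw_error": est.raw_error,
                     "normalized_error": est.normalized_error,
                     "p_value": est.p_value})
        pd.concat(all_trials, ignore_index=True).to_csv(out / "ratings.csv", index=False)
        (out / "similarity_results.json").write_text(json.dumps(results, indent=2))
        log.info("similarity: %d observers, factor sets %s", config.n_observers,
                 list(results))

    if "fg" in config.stages:
        sel = selected_cues()
        if not patches:
            load_corpus()
        for c in sel:
            frames.setdefault(c.patch_id, local_frame(patches[c.patch_id]))
        sel = [c for c in sel if not frames[c.patch_id].degenerate]
        rng = np.random.default_rng(seeds["fg"])
        frames_list = [frames[c.patch_id] for c in sel]
        all_resp = []
        for k in range(config.n_observers):
            model = ObserverModel(fg_weights=tuple(config.fg_weights),
                                  seed=int(rng.integers(2**31)),
                                  observer_id=f"obs{k}")
            all_resp.append(simulate_fg(sel, frames_list, model,
                                        n_reps=config.n_fg_reps))
        responses = pd.concat(all_resp, ignore_index=True)
        responses.to_csv(out / "responses.csv", index=False)
        table = convex_choice_rate(responses, {c.patch_id: frames[c.patch_id] for c in sel})
        table.table.to_csv(out / "choice_table.csv", index=False)
        answered = [c for c in sel if c.patch_id in set(table.table.patch_id)]
        reg = mlra(table, answered)
        (out / "fg_regression.json").write_text(json.dumps({
            "coefficients": reg.coefficients, "p_values": reg.p_values,
            "adjusted_r2": reg.adjusted_r2, "n_patches": reg.n_patches,
            "n_excluded_degenerate": reg.n_excluded_degenerate}, indent=2))
        log.info("fg: %d patches regressed", reg.n_patches)

    log.info("run complete: %s", out)
    return out


@dataclass
class ValidationReport:
    path: str
    schema: str
    n_rows: int
    violations: list


_SCHEMAS = {
    "ratings": ["observer_id", "stimulus_a", "stimulus_b", "repetition", "rating"],
    "responses": ["observer_id", "patch_id", "repetition", "group", "answer"],
    "cues": ["patch_id", "convexity", "closure", "symmetry", "orientation_deg",
             "orientation_bin", "theta_star", "x_star", "dos_star", "degenerate_flag"],
}


def validate_io(path, schema: str) -> ValidationReport:
    """Schema check for a pipeline artifact; reports row count and violations."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    violations: list[str] = []
    if schema == "dissimilarity":
        m = np.loadtxt(path, delimiter=",")
        n = m.shape[0] if m.ndim == 2 else 0
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            violations.append("matrix is not square")
        else:
            if not np.allclose(m, m.T):
                violations.append("matrix is not symmetric")
            if not np.allclose(np.diag(m), 0):
                violations.append("diagonal is not zero")
            if (m < 0).any():
                violations.append("negative dissimilarity")
        return ValidationReport(str(path), schema, n, violations)
    if schema not in _SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}")
    df = pd.read_csv(path)
    missing = [c for c in _SCHEMAS[schema] if c not in df.columns]
    for c in missing:
        violations.append(f"missing column {c!r}")
    if schema == "ratings" and "rating" in df.columns:
        bad = df[(df.rating < 1) | (df.rating > 5)]
        if len(bad):
            violations.append(f"rating out of 1-5 in {len(bad)} rows")
    if schema == "responses" and {"group", "answer"} <= set(df.columns):
        from .synth import GROUP_ANSWERS

        for g, sub in df.groupby("group"):
            if g not in GROUP_ANSWERS:
                violations.append(f"unknown group {g!r}")
                continue
            bad = set(sub["answer"]) - set(GROUP_ANSWERS[g])
            if bad:
                violations.append(f"answer {sorted(bad)} invalid for group {g!r}")
    return ValidationReport(str(path), schema, len(df), violations)
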