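"""End-to-end orchestration: simulate -> fit -> ALPS -> PET quant -> stats.

A run is driven by a :class:`RunConfig` (YAML or dict), executes its
stages in dependency order into an output directory, and writes a
``manifest.json`` recording the configuration, seeds, package version and
the SHA-256 of every file produced.  Identical config and seed give
identical output hashes; on a stage failure the partial outputs are kept
next to a ``FAILED`` marker naming the stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .alps import compute_subject_alps, result_row
from .cohort import CohortSpec, simulate_cohort
from .dti import TensorModel, split_shells
from .io import write_gradient_table, write_mask, write_volume
from .pet import CentiloidAnchors, PetMeta, quantify
from .phantom import PhantomSpec, alps_protocol, make_tensor_phantom, \
    simulate_dwi, simulate_pet_suvr
from .stats import CohortModel

__all__ = ["RunConfig", "ConfigError", "StageError", "validate_config", "run_pipeline"]


class ConfigError(ValueError):
    """Invalid or unresolvable run configuration (CLI exit code 2)."""


class StageError(RuntimeError):
    """A pipeline stage failed (CLI exit code 3)."""


@dataclass
class RunConfig:
    """Typed scenario for a full run.

    ``phantom``/``protocol``/``cohort``/``pet`` blocks override the shipped
    defaults; unknown keys are rejected so typos fail loudly.
    """

    seed: int
    outdir: str
    phantom: dict = field(default_factory=dict)
    protocol: dict = field(default_factory=dict)
    cohort: dict | None = None          # None -> shipped study defaults
    pet: dict = field(default_factory=dict)
    stages: tuple[str, ...] = ("phantom", "pet", "cohort")

    _PHANTOM_KEYS = {"shape", "spacing", "perivascular_gain", "s0", "snr"}
    _PROTOCOL_KEYS = {"n_dirs", "shells", "n_b0"}
    _PET_KEYS = {"target_centiloid", "suvr_yc", "suvr_ad100",
                 "injected_dose_mbq", "body_weight_kg"}

    def __post_init__(self):
        if not isinstance(self.seed, int):
            raise ConfigError(f"seed must be an integer, got {self.seed!r}")
        for block, allowed in (("phantom", self._PHANTOM_KEYS),
                               ("protocol", self._PROTOCOL_KEYS),
                               ("pet", self._PET_KEYS)):
            extra = set(getattr(self, block) or {}) - allowed
            if extra:
                raise ConfigError(f"unknown key(s) {sorted(extra)} in {block!r} block")
        bad = set(self.stages) - {"phantom", "pet", "cohort"}
        if bad:
            raise ConfigError(f"unknown stage(s) {sorted(bad)}")

    def phantom_spec(self) -> PhantomSpec:
        kw = dict(self.phantom or {})
        for key in ("shape", "spacing"):
            if key in kw:
                kw[key] = tuple(kw[key])
        try:
            return PhantomSpec(**kw)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"phantom block: {exc}") from exc

    def gradient_table(self):
        kw = dict(self.protocol or {})
        if "shells" in kw:
            kw["shells"] = tuple(float(b) for b in kw["shells"])
        return alps_protocol(**kw)

    def cohort_spec(self) -> CohortSpec:
        if self.cohort is None:
            return CohortSpec.study_defaults()
        try:
            return CohortSpec.from_dict(self.cohort)
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigError(f"cohort block: {exc}") from exc

    def anchors(self) -> CentiloidAnchors:
        kw = {k: v for k, v in (self.pet or {}).items()
              if k in ("suvr_yc", "suvr_ad100")}
        return CentiloidAnchors(**kw) if kw else CentiloidAnchors()


def validate_config(path: str | Path) -> RunConfig:
    """Load and range-check a YAML/JSON scenario file."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file {path} does not exist")
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping")
    known = {f.name for f in dataclasses.fields(RunConfig) if not f.name.startswith("_")}
    extra = set(raw) - known
    if extra:
        raise ConfigError(f"unknown top-level key(s): {sorted(extra)}")
    missing = {"seed", "outdir"} - set(raw)
    if missing:
        raise ConfigError(f"missing required key(s): {sorted(missing)}")
    if "stages" in raw:
        raw["stages"] = tuple(raw["stages"])
    cfg = RunConfig(**raw)
    # fail fast on bad blocks, before any stage runs
    cfg.phantom_spec(), cfg.gradient_table(), cfg.cohort_spec(), cfg.anchors()
    return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns the manifest dict.

    Stage seeds are derived deterministically from ``config.seed`` with
    ``numpy.random.SeedSequence.spawn``, so adding or removing a stage does
    not shift another stage's stream.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = {name: np.random.default_rng(s)
             for name, s in zip(("phantom", "pet", "cohort"),
                                np.random.SeedSequence(config.seed).spawn(3))}
    manifest: dict = {
        "glymph_version": __version__,
        "seed": config.seed,
        "config": {
            "phantom": config.phantom, "protocol": config.protocol,
            "cohort": config.cohort, "pet": config.pet,
            "stages": list(config.stages),
        },
        "stages": {},
        "outputs": {},
    }

    def record(stage: str, paths: list[Path], t0: float) -> None:
        manifest["stages"][stage] = {
            "status": "ok",
            "elapsed_s": round(time.monotonic() - t0, 3),
            "outputs": [p.name for p in paths],
        }
        for p in paths:
            manifest["outputs"][p.name] = _sha256(p)

    current = "setup"
    try:
        if "phantom" in config.stages:
            current = "phantom"
            t0 = time.monotonic()
            spec = config.phantom_spec()
            table = config.gradient_table()
            phantom = make_tensor_phantom(spec)
            dwi = simulate_dwi(phantom.field, table, s0=spec.s0, snr=spec.snr,
                               rng=seeds["phantom"])
            paths = [
                write_volume(dwi, outdir / "dwi.nii"),
                write_mask(phantom.mask, outdir / "rois.nii",
                           outdir / "rois.json"),
            ]
            paths.append(outdir / "rois.json")
            write_gradient_table(table, outdir / "dwi.bval", outdir / "dwi.bvec")
            paths += [outdir / "dwi.bval", outdir / "dwi.bvec"]
            rows = []
            for b, (sdwi, stab) in split_shells(dwi, table).items():
                fit = TensorModel(stab).fit(sdwi)
                res, rois = compute_subject_alps(fit, phantom.mask)
                rows.append(result_row("phantom", res, rois)
                            | {"analytic_alps": phantom.analytic_alps})
            alps_path = outdir / "alps.tsv"
            _write_tsv(pd.DataFrame(rows), alps_path)
            paths.append(alps_path)
            record("phantom", paths, t0)

        if "pet" in config.stages:
            current = "pet"
            t0 = time.monotonic()
            pet_cfg = config.pet or {}
            target = float(pet_cfg.get("target_centiloid", 78.5))
            anchors = config.anchors()
            mask = make_tensor_phantom(config.phantom_spec()).mask
            suvr = simulate_pet_suvr(mask, target, anchors)
            # activity consistent with the SUVR map and the injection meta
            meta = PetMeta(float(pet_cfg.get("injected_dose_mbq", 725.0)),
                           float(pet_cfg.get("body_weight_kg", 60.0)))
            activity = suvr.with_data(
                suvr.data * (meta.injected_dose_mbq / meta.body_weight_kg),
                units="kBq/mL")
            row = quantify(activity, meta, mask, anchors)
            row["target_centiloid"] = target
            paths = [write_volume(suvr, outdir / "suvr.nii")]
            pet_path = outdir / "pet_quant.tsv"
            _write_tsv(pd.DataFrame([row]), pet_path)
            paths.append(pet_path)
            record("pet", paths, t0)

        if "cohort" in config.stages:
            current = "cohort"
            t0 = time.monotonic()
            spec = config.cohort_spec()
            table = simulate_cohort(spec, seeds["cohort"])
            results = CohortModel(table).fit()
            paths = []
            for name, df in (("cohort.tsv", table),
                             ("group_summary.tsv", results.group_summary.reset_index()),
                             ("regressions.tsv", results.regressions),
                             ("normalized_slopes.tsv",
                              results.normalized.reset_index())):
                _write_tsv(df, outdir / name)
                paths.append(outdir / name)
            (outdir / "summary.txt").write_text(results.summary() + "\n")
            paths.append(outdir / "summary.txt")
            record("cohort", paths, t0)
    except (ConfigError,):
        raise
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage {current}: {exc}\n")
        raise StageError(f"stage {current!r} failed: {exc}") from exc

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
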