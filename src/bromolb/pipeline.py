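"""End-to-end orchestration: phantom/cohort generation, per-case BROM-OLB
assessment, exclusion accounting, diagnostics, and reproducible file I/O.

A study run is a pure function of its :class:`RunConfig` (identical config,
identical results bytes, timestamps excluded). Per-case seeds are derived
from the global seed with ``numpy.random.SeedSequence`` spawn keys, so case
order never changes results.

NIfTI conventions: in-memory arrays are (z, y, x); on disk the array is
transposed to NIfTI's (x, y, z) with the voxel spacing on the affine
diagonal. HU values round-trip exactly (float64).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .broml import BromOlbConfig, assess_case
from .diagnostics import (build_table, diagnostic_metrics, logistic_fit,
                          mann_whitney_u, roc_analysis)
from .errors import ConfigError, SeparationError, ValidationError
from .phantom import (COHORT_COLUMNS, CaseRecord, CohortSimParams, CTVolume,
                      PhantomParams, TruthMasks, cohort_to_frame,
                      generate_cohort, generate_phantom)

log = logging.getLogger("bromolb")

_VERSION = "0.1.0"


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RunConfig:
    """Complete, serializable description of one study run."""

    cohort: CohortSimParams = field(default_factory=CohortSimParams)
    phantom: PhantomParams = field(default_factory=PhantomParams)
    broml: BromOlbConfig = field(default_factory=BromOlbConfig)
    source: str = "parametric"        # "parametric" or "phantom"
    n_phantom_cases: int = 12         # cases rendered when source == "phantom"
    seed: int = 0
    out_dir: str | None = None
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.source not in ("parametric", "phantom"):
            raise ConfigError(f"unknown cohort source {self.source!r}")
        self.cohort.validate()
        self.phantom.validate()
        self.broml.validate()

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key, typ in (("cohort", CohortSimParams), ("phantom", PhantomParams),
                         ("broml", BromOlbConfig)):
            if key in d and isinstance(d[key], dict):
                try:
                    d[key] = typ(**{k: tuple(v) if isinstance(v, list) else v
                                    for k, v in d[key].items()})
                except TypeError as err:
                    raise ConfigError(f"bad {key} section: {err}") from err
        try:
            return cls(**d)
        except TypeError as err:
            raise ConfigError(str(err)) from err

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


@dataclass
class RunManifest:
    """Accounting for one run: files, per-case status, exclusions, provenance."""

    config_hash: str
    software_version: str
    n_cases_in: int
    n_cases_evaluated: int
    n_cases_excluded: int
    exclusion_reasons: dict[str, int]
    case_status: dict[str, str]       # case_id -> "evaluated" | reason
    files: dict[str, str]


# ---------------------------------------------------------------------------
# volume / cohort I/O
# ---------------------------------------------------------------------------

def write_volume(volume: CTVolume, path: str | Path) -> None:
    """Write a CTVolume as NIfTI with the spacing in the header."""
    sz, sy, sx = volume.spacing
    affine = np.diag([sx, sy, sz, 1.0])
    img = nib.Nifti1Image(volume.voxels.transpose(2, 1, 0).astype(np.float64), affine)
    img.header.set_zooms((sx, sy, sz))
    nib.save(img, str(path))


def read_volume(path: str | Path, gravity_axis=(0.0, 1.0, 0.0),
                lung_threshold_hu: float = -400.0) -> CTVolume:
    """Read a NIfTI volume back into (z, y, x) order.

    The lung mask is recovered by thresholding (voxels below
    ``lung_threshold_hu``), which is exact for phantoms.
    """
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64).transpose(2, 1, 0)
    sx, sy, sz = img.header.get_zooms()[:3]
    lung = data < lung_threshold_hu
    from scipy import ndimage
    pleura = lung & ~ndimage.binary_erosion(lung)
    return CTVolume(voxels=data, spacing=(float(sz), float(sy), float(sx)),
                    gravity_axis=np.asarray(gravity_axis, dtype=float),
                    lung_mask=lung, pleura_surface=pleura)


_MASK_LABELS = {"lesion": 1, "emphysema": 2, "ground_glass": 3, "normal_parenchyma": 4}


def write_masks(masks: TruthMasks, path: str | Path,
                spacing=(1.0, 1.0, 1.0)) -> None:
    """Write truth masks as one integer-labelled NIfTI (see _MASK_LABELS)."""
    lab = np.zeros(masks.lesion.shape, dtype=np.uint8)
    for name, value in _MASK_LABELS.items():
        lab[getattr(masks, name)] = value
    sz, sy, sx = spacing
    nib.save(nib.Nifti1Image(lab.transpose(2, 1, 0), np.diag([sx, sy, sz, 1.0])),
             str(path))


def read_masks(path: str | Path) -> TruthMasks:
    img = nib.load(str(path))
    lab = np.asarray(img.dataobj).transpose(2, 1, 0)
    return TruthMasks(**{name: lab == value for name, value in _MASK_LABELS.items()})


def write_cohort(records, path: str | Path) -> None:
    """Write a cohort as CSV with the documented column dictionary."""
    df = records if isinstance(records, pd.DataFrame) else cohort_to_frame(records)
    df.to_csv(path, index=False)


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read and validate a cohort CSV; failures name the offending field."""
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"cohort CSV missing columns: {missing}")
    bad = ~df["hemorrhage_grade"].isin([0, 1, 2, 3, 4])
    if bad.any():
        raise ValidationError(
            "field 'hemorrhage_grade' outside 0-4 for cases "
            f"{df.loc[bad, 'case_id'].tolist()}")
    bools = [c for c in COHORT_COLUMNS if c.startswith(("brom_", "minip_le", "lw_le"))]
    bools += ["general_emphysema", "emphysema_lar", "pneumothorax"]
    for c in bools:
        df[c] = df[c].astype(bool)
    bad = df["lw_value"] < df["minip_value"]
    if bad.any():
        raise ValidationError(
            f"field 'lw_value' below 'minip_value' for cases "
            f"{df.loc[bad, 'case_id'].tolist()}")
    return df


# ---------------------------------------------------------------------------
# study orchestration
# ---------------------------------------------------------------------------

def _case_seed(global_seed: int, i: int) -> int:
    ss = np.random.SeedSequence(entropy=global_seed, spawn_key=(i,))
    return int(ss.generate_state(1)[0] % (2 ** 31))

def _phantom_cohort(config: RunConfig) -> tuple[list[CaseRecord], dict[str, str]]:
    """Render one phantom per case, assess it, then draw outcomes from the
    logistic models using the measured densities and calls."""
    from scipy.special import expit

    cp = config.cohort
    status: dict[str, str] = {}
    records: list[CaseRecord] = []
    positions = ["supine", "lateral", "prone"]
    rng = np.random.default_rng(_case_seed(config.seed, 10_000_019))
    for i in range(config.n_phantom_cases):
        cid = f"case-{i:05d}"
        seed = _case_seed(config.seed, i)
        pparams = dataclasses.replace(
            config.phantom, seed=seed,
            patient_position=positions[i % 3],
            emphysema_placement="on_route" if i % 2 == 0 else "off_route")
        vol, masks, path = generate_phantom(pparams)
        a = assess_case(vol, masks, path, config.broml)
        if not a.evaluable:
            status[cid] = a.unevaluable_reason
            continue
        time = max(float(rng.normal(cp.time_mean, cp.time_sd)), 5.0)
        p_ptx = expit(cp.ptx_intercept + cp.ptx_coef_bromolb * a.positive_minip
                      + cp.ptx_coef_time * time)
        p_hem = expit(cp.hem_intercept + cp.hem_coef_lw * a.lw_value)
        hem2 = rng.random() < p_hem
        grade = int(rng.choice([2, 3, 4], p=[.85, .10, .05])) if hem2 \
            else int(rng.choice([0, 1], p=[1 / 52, 51 / 52]))
        records.append(CaseRecord(
            case_id=cid, patient_position=pparams.patient_position,
            lesion_size=2 * config.phantom.lesion_radius_mm,
            procedure_time=time,
            lw_value=a.lw_value, minip_value=a.minip_value,
            brom_olb_lw=a.positive_lw, brom_olb_minip=a.positive_minip,
            minip_le_850=a.minip_le_850, lw_le_850=a.lw_le_850,
            general_emphysema=config.phantom.n_emphysema_clusters > 0,
            emphysema_lar=pparams.emphysema_placement == "on_route",
            pneumothorax=bool(rng.random() < p_ptx),
            hemorrhage_grade=grade,
        ))
        status[cid] = "evaluated"
    return records, status


_CLASSIFIERS = ["brom_olb_minip", "brom_olb_lw", "minip_le_850", "lw_le_850"]


def run_study(config: RunConfig) -> tuple[RunManifest, dict]:
    """Generate a cohort, assess it, run the diagnostics, write the bundle.

    Returns the manifest and the results dictionary. Per-case failures are
    isolated and counted as exclusions; only configuration errors abort.
    """
    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))

    if config.source == "parametric":
        if config.cohort.n_cases == 0:
            records = []
        else:
            records = generate_cohort(dataclasses.replace(config.cohort,
                                                          seed=config.seed))
        status = {r.case_id: "evaluated" for r in records}
    else:
        records, status = _phantom_cohort(config)

    n_in = len(status)
    excluded = {cid: s for cid, s in status.items() if s != "evaluated"}
    reasons: dict[str, int] = {}
    for s in excluded.values():
        reasons[s] = reasons.get(s, 0) + 1

    results: dict = {
        "n_cases_in": n_in,
        "n_cases_evaluated": len(records),
        "n_cases_excluded": len(excluded),
        "exclusion_reasons": reasons,
    }
    df = cohort_to_frame(records) if records else pd.DataFrame(columns=COHORT_COLUMNS)

    if len(records):
        results["pneumothorax_rate"] = float(df["pneumothorax"].mean())
        results["hemorrhage_ge2_rate"] = float((df["hemorrhage_grade"] >= 2).mean())
        tables = {}
        for clf in _CLASSIFIERS:
            try:
                t = build_table(df, "pneumothorax", clf)
                m = diagnostic_metrics(t)
                tables[clf] = {
                    "tp": t.tp, "fn": t.fn, "fp": t.fp, "tn": t.tn,
                    "sensitivity": m.sensitivity, "specificity": m.specificity,
                    "auc": m.auc, "phi": m.phi, "fisher_p": m.fisher_p,
                }
            except ValidationError as err:
                tables[clf] = {"error": str(err)}
        results["classifier_tables"] = tables

        for col, key in (("minip_value", "minip"), ("lw_value", "lw")):
            grp_e = df.loc[df["pneumothorax"], col]
            grp_n = df.loc[~df["pneumothorax"], col]
            if len(grp_e) and len(grp_n):
                u, p = mann_whitney_u(grp_e, grp_n)
                results[f"mwu_{key}_by_ptx"] = {"U": u, "p": p}
                roc = roc_analysis(df[col], df["pneumothorax"])
                results[f"roc_{key}"] = {
                    "auc": roc.auc,
                    "youden_threshold_hu": roc.youden_threshold,
                    "top_left_threshold_hu": roc.top_left_threshold,
                }

        for name, design_cols, outcome in (
                ("logit_pneumothorax", ["brom_olb_minip", "procedure_time"],
                 df["pneumothorax"]),
                ("logit_hemorrhage", ["lw_value"], df["hemorrhage_grade"] >= 2)):
            try:
                fit = logistic_fit(df[design_cols].astype(float), outcome.astype(int))
                results[name] = {
                    "names": fit.names,
                    "B": fit.coef.tolist(), "SE": fit.se.tolist(),
                    "OR": fit.odds_ratios.tolist(),
                    "ci_low": fit.ci_low.tolist(), "ci_high": fit.ci_high.tolist(),
                    "p": fit.p_values.tolist(),
                    "nagelkerke_r2": fit.nagelkerke_r2, "cohens_f2": fit.cohens_f2,
                }
            except (SeparationError, ValidationError) as err:
                results[name] = {"error": str(err)}

    files: dict[str, str] = {}
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_cohort(df, out / "cohort.csv")
        (out / "results.json").write_text(
            json.dumps(results, indent=2, sort_keys=True) + "\n")
        config.to_yaml(out / "config.yaml")
        files = {"cohort": str(out / "cohort.csv"),
                 "results": str(out / "results.json"),
                 "config": str(out / "config.yaml")}

    manifest = RunManifest(
        config_hash=config.config_hash(), software_version=_VERSION,
        n_cases_in=n_in, n_cases_evaluated=len(records),
        n_cases_excluded=len(excluded), exclusion_reasons=reasons,
        case_status=status, files=files,
    )
    if config.out_dir is not None:
        (Path(config.out_dir) / "manifest.json").write_text(
            json.dumps(dataclasses.asdict(manifest), indent=2, sort_keys=True) + "\n")
    return manifest, results
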