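"""End-to-end orchestration: structures -> descriptors -> split -> FFD/PLS ->
validation -> applicability domain -> interpretation.

Every stage reads and writes plain files (SDF/CSV/JSON/cube), each run
directory carries a ``manifest.json`` recording the configuration hash and
seed, and stage outputs embed that hash so mixed-provenance inputs are
rejected.  A rerun with the same configuration and seed reproduces all
numeric outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import structures
from .feature_selection import ffd_select
from .grind import DescriptorMatrix
from .model import GrindPLS
from .simulate import SimulationConfig, compute_descriptors, generate_dataset
from .splitting import make_split
from .validation import plot_williams

log = logging.getLogger("grindqsar.pipeline")


@dataclass
class RunConfig:
    structures_path: str = "structures.sdf"
    activities_path: str = "activities.csv"
    output_dir: str = "qsar_run"
    spacing: float = 0.5          # grid spacing, A
    margin: float = 5.0           # grid margin, A
    probe_params_path: str | None = None
    n_nodes: int = 100
    node_w: float = 0.5
    bin_width: float = 0.4        # A
    max_distance: float = 25.0    # A
    scaling: str = "pareto"
    min_nonzero_fraction: float = 0.25
    a_max: int = 5
    ffd: bool = True
    ffd_dummy_fraction: float = 0.2
    ffd_cv_groups: int = 5
    ffd_components: int = 2
    n_test: int = 15
    seed: int = 0
    ad_intercept: bool = True     # include 1/n in leverages
    top_n_variables: int = 10

    def __post_init__(self):
        for name in ("spacing", "margin", "bin_width", "max_distance"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 <= self.node_w <= 1:
            raise ValueError("node_w must lie in [0, 1]")

    @property
    def config_hash(self) -> str:
        doc = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(doc.encode()).hexdigest()[:16]

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for key, value in dataclasses.asdict(self).items():
                fh.write(f"{key}={value}\n")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        kwargs = {}
        fields = {f.name: f for f in dataclasses.fields(cls)}
        with open(path) as fh:
            for raw in fh:
                line = raw.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, value = line.partition("=")
                key = key.strip()
                if key not in fields:
                    raise ValueError(f"unknown config key {key!r}")
                ftype = fields[key].type
                if value.strip() == "None":
                    kwargs[key] = None
                elif "bool" in str(ftype):
                    kwargs[key] = value.strip().lower() in ("1", "true", "yes")
                elif "int" in str(ftype):
                    kwargs[key] = int(value)
                elif "float" in str(ftype):
                    kwargs[key] = float(value)
                else:
                    kwargs[key] = value.strip()
        return cls(**kwargs)

    def sim_config(self, **overrides) -> SimulationConfig:
        base = dict(spacing=self.spacing, margin=self.margin,
                    n_nodes=self.n_nodes, node_w=self.node_w,
                    bin_width=self.bin_width, max_distance=self.max_distance,
                    seed=self.seed)
        base.update(overrides)
        return SimulationConfig(**base)


# ---------------------------------------------------------------------------
# Manifest helpers
# ---------------------------------------------------------------------------

def _manifest_path(outdir: Path) -> Path:
    return outdir / "manifest.json"

def load_manifest(outdir) -> dict:
    path = _manifest_path(Path(outdir))
    if path.exists():
        with open(path) as fh:
            return json.load(fh)
    return {}


def update_manifest(outdir, config: RunConfig, **entries) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = load_manifest(outdir)
    prev_hash = manifest.get("config_hash")
    if prev_hash is not None and prev_hash != config.config_hash:
        raise ValueError(
            f"output directory {outdir} was produced with a different "
            f"configuration (hash {prev_hash} != {config.config_hash}); "
            "refusing to mix provenance")
    manifest.update({"config_hash": config.config_hash, "seed": config.seed,
                     "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S")})
    files = manifest.setdefault("files", {})
    files.update({k: str(v) for k, v in entries.items()})
    with open(_manifest_path(outdir), "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def _check_hash(path, config: RunConfig) -> None:
    """Reject a stage input carrying a foreign config hash."""
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("# config_hash=") :
        found = first.strip().split("=", 1)[1]
        if found != config.config_hash:
            raise ValueError(f"{path} was produced under config hash {found}, "
                             f"current is {config.config_hash}")


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_simulate(config: RunConfig, sim_overrides: dict | None = None):
    """Generate a synthetic dataset and write SDF + activity CSV."""
    t0 = time.time()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    ds = generate_dataset(config.sim_config(**(sim_overrides or {})))
    sdf = outdir / config.structures_path
    csv = outdir / config.activities_path
    structures.write_sdf(ds.molecules, sdf)
    structures.write_activity_table(ds.activities, csv, config.config_hash)
    update_manifest(outdir, config, structures=sdf.name, activities=csv.name)
    log.info("simulate: %d compounds in %.1fs", len(ds.molecules), time.time() - t0)
    return ds


def load_inputs(config: RunConfig):
    outdir = Path(config.output_dir)
    sdf = outdir / config.structures_path
    if not sdf.exists():
        sdf = Path(config.structures_path)
    csv = outdir / config.activities_path
    if not csv.exists():
        csv = Path(config.activities_path)
    mols = [structures.prepare(m) for m in structures.read_sdf(sdf)]
    table = structures.read_activity_table(csv)
    return mols, table


def stage_encode(config: RunConfig):
    """SDF -> probe fields -> nodes -> descriptor CSV."""
    t0 = time.time()
    outdir = Path(config.output_dir)
    mols, _ = load_inputs(config)
    sim = config.sim_config()
    from .params import load_probe_params
    probes = load_probe_params(config.probe_params_path)
    dm = compute_descriptors(mols, sim, probes=probes)
    path = outdir / "descriptors.csv"
    dm.to_csv(path, config_hash=config.config_hash)
    update_manifest(outdir, config, descriptors=path.name)
    log.info("encode: %d x %d descriptors in %.1fs",
             *dm.values.shape, time.time() - t0)
    return dm


def stage_split(config: RunConfig):
    outdir = Path(config.output_dir)
    table = structures.read_activity_table(outdir / config.activities_path)
    split = make_split(table, n_test=config.n_test, seed=config.seed)
    table = split.apply(table)
    path = outdir / config.activities_path
    structures.write_activity_table(table, path, config.config_hash)
    update_manifest(outdir, config, activities=path.name)
    log.info("split: %d train / %d test", split.n_train, split.n_test)
    return split


def stage_fit(config: RunConfig, dm: DescriptorMatrix | None = None,
              table: pd.DataFrame | None = None):
    outdir = Path(config.output_dir)
    if dm is None:
        _check_hash(outdir / "descriptors.csv", config)
        dm = DescriptorMatrix.from_csv(outdir / "descriptors.csv",
                                       config.bin_width, config.max_distance)
    if table is None:
        table = structures.read_activity_table(outdir / config.activities_path)
    if "set" not in table.columns or not (table["set"] == "train").any():
        raise ValueError("activity table has no training set; run split first")
    train_ids = table.loc[table["set"] == "train", "id"].astype(str).tolist()

    spec = GrindPLS.from_descriptor_matrix(dm, table, ids=train_ids,
                                           scaling=config.scaling)
    results = spec.fit(
        n_components=None, a_max=config.a_max, ffd=config.ffd,
        ffd_seed=config.seed,
        min_nonzero_fraction=config.min_nonzero_fraction,
        ffd_kwargs=dict(dummy_fraction=config.ffd_dummy_fraction,
                        n_cv_groups=config.ffd_cv_groups,
                        n_components=config.ffd_components))
    path = outdir / "model.json"
    cols = [dm.meta[i].column for i in results.selected]
    doc = results.plsfit.to_json(variable_columns=cols,
                                 config_hash=config.config_hash)
    doc["selected_indices"] = results.selected.tolist()
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
    update_manifest(outdir, config, model=path.name)
    log.info("fit: %d variables, %d components, R2=%.3f Q2=%.3f",
             len(results.selected), results.n_components,
             results.rsquared, results.q2_loo)
    return results


def stage_validate(config: RunConfig, results, dm: DescriptorMatrix,
                   table: pd.DataFrame):
    outdir = Path(config.output_dir)
    test_ids = table.loc[table["set"] == "test", "id"].astype(str).tolist()
    if len(test_ids) >= 3:
        act = table.set_index(table["id"].astype(str))["pIC50"]
        y_test = act.loc[test_ids].to_numpy(float)
        results.validate_external(y_test, dm.rows(test_ids))
    path = outdir / "validation_report.json"
    results.report.to_json(path, config_hash=config.config_hash)
    txt = outdir / "validation_report.txt"
    with open(txt, "w") as fh:
        fh.write(f"# config_hash={config.config_hash}\n")
        fh.write(results.report.summary_table() + "\n")
    update_manifest(outdir, config, validation=path.name, validation_text=txt.name)
    return results.report


def stage_ad(config: RunConfig, results, dm: DescriptorMatrix,
             table: pd.DataFrame, plot: bool = True):
    outdir = Path(config.output_dir)
    test_ids = table.loc[table["set"] == "test", "id"].astype(str).tolist()
    act = table.set_index(table["id"].astype(str))["pIC50"]
    kwargs = {}
    if test_ids:
        kwargs = dict(exog_test=dm.rows(test_ids),
                      endog_test=act.loc[test_ids].to_numpy(float),
                      ids_test=test_ids)
    wd = results.williams(include_intercept=config.ad_intercept, **kwargs)
    path = outdir / "williams.csv"
    wd.to_csv(path, config_hash=config.config_hash)
    entries = {"williams": path.name}
    if plot:
        png = outdir / "williams.png"
        plot_williams(wd, png)
        entries["williams_plot"] = png.name
    update_manifest(outdir, config, **entries)
    return wd


def stage_report(config: RunConfig, results, dm: DescriptorMatrix,
                 table: pd.DataFrame, wd=None):
    from .interpret import variable_report_frame
    outdir = Path(config.output_dir)
    entries = results.rank_variables(config.top_n_variables)
    vr = outdir / "variable_report.csv"
    with open(vr, "w") as fh:
        fh.write(f"# config_hash={config.config_hash}\n")
        variable_report_frame(entries).to_csv(fh, index=False)

    ids = table["id"].astype(str).tolist()
    preds = results.predict(dm.rows(ids))
    pred_df = pd.DataFrame({"id": ids, "pIC50_pred": np.round(preds, 6),
                            "set": table["set"]})
    if wd is not None:
        ad_map = wd.table.set_index("id")["outside_ad"]
        pred_df["in_AD"] = ~pred_df["id"].map(ad_map).fillna(False).astype(bool)
    pr = outdir / "predictions.csv"
    with open(pr, "w") as fh:
        fh.write(f"# config_hash={config.config_hash}\n")
        pred_df.to_csv(fh, index=False)
    update_manifest(outdir, config, variable_report=vr.name, predictions=pr.name)
    return entries, pred_df


def _write_pca(config: RunConfig, dm: DescriptorMatrix, k: int = 2) -> None:
    """Dataset overview PCA (computed before partitioning)."""
    from .pls import pca_scores
    X = dm.values[:, dm.values.std(axis=0) > 0]
    k = min(k, min(X.shape))
    scores, frac = pca_scores(X, k, scaling=config.scaling)
    out = pd.DataFrame(scores, columns=[f"PC{i + 1}" for i in range(k)])
    out.insert(0, "id", dm.ids)
    path = Path(config.output_dir) / "pca_scores.csv"
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config.config_hash}\n")
        fh.write("# explained_variance_fractions="
                 + ",".join(f"{f:.6f}" for f in frac) + "\n")
        out.to_csv(fh, index=False)
    update_manifest(Path(config.output_dir), config, pca=path.name)


def run_all(config: RunConfig, simulate: bool = False,
            sim_overrides: dict | None = None) -> dict:
    """Run the full pipeline; on stage failure a FAILED marker is written
    and the exception re-raised (partial outputs are preserved)."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        if simulate:
            stage = "simulate"
            stage_simulate(config, sim_overrides)
        stage = "encode"
        dm = stage_encode(config)
        stage = "pca"
        _write_pca(config, dm)
        stage = "split"
        stage_split(config)
        table = structures.read_activity_table(outdir / config.activities_path)
        stage = "fit"
        results = stage_fit(config, dm, table)
        stage = "validate"
        report = stage_validate(config, results, dm, table)
        stage = "ad"
        wd = stage_ad(config, results, dm, table)
        stage = "report"
        entries, preds = stage_report(config, results, dm, table, wd)
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage {stage}: {exc}\n")
        raise
    config.to_file(outdir / "config.txt")
    return {"descriptors": dm, "results": results, "report": report,
            "williams": wd, "variables": entries, "predictions": preds,
            "output_dir": outdir}
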