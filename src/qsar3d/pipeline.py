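"""Config-driven end-to-end QSAR run.

The workflow mirrors the standard lattice-QSAR protocol: align the
series on the common anchor, compute the requested field blocks on an
automatically sized grid, filter low-variance columns, pick the
component count by LOO q², fit the final PLS model, compute the
internal/external statistics tables, run bootstrap and y-randomisation
robustness checks, and export StDev*Coeff contour maps. Everything is
deterministic given the config seed.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import chem_io, fields, pls_model, validation
from .alignment import DEFAULT_ANCHOR, align_dataset
from .chem_io import QsarDataset
from .contours import export_dx, make_contour_set
from .fields import COMSIA_KINDS

logger = logging.getLogger("qsar3d")

__all__ = ["RunConfig", "run_qsar", "field_combination_sweep", "prepare_descriptors"]


@dataclass
class RunConfig:
    """All knobs of one pipeline run; unknown config keys are rejected."""

    molecules: str | None = None  # SDF/MOL2 path
    activities: str | None = None  # CSV path
    split: str | None = None  # test-id list path
    anchor: str = DEFAULT_ANCHOR
    template_id: str | None = None  # default: most potent training compound
    method: str = "comfa"  # comfa | comsia | both
    comsia_kinds: tuple[str, ...] = COMSIA_KINDS
    spacing: float = 2.0
    margin: float = 4.0
    min_sigma: float = 0.0
    scaling: str = "block"
    max_pcs: int = 10
    n_bootstrap: int = 100
    n_randomization: int = 50
    favored_pct: float = 80.0
    disfavored_pct: float = 20.0
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.method not in ("comfa", "comsia", "both"):
            raise ValueError(f"unknown method {self.method!r}")
        unknown = set(self.comsia_kinds) - set(COMSIA_KINDS)
        if unknown:
            raise ValueError(f"unknown CoMSIA field kinds: {sorted(unknown)}")
        if self.spacing <= 0 or self.margin < 0 or self.min_sigma < 0:
            raise ValueError("spacing/margin/min_sigma out of range")
        if self.max_pcs < 1:
            raise ValueError("max_pcs must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "comsia_kinds" in raw:
            raw["comsia_kinds"] = tuple(raw["comsia_kinds"])
        return cls(**raw)


def _load_dataset(config: RunConfig) -> QsarDataset:
    if config.molecules is None or config.activities is None or config.split is None:
        raise ValueError("config needs molecules, activities and split paths")
    mols = chem_io.read_molecules(config.molecules)
    acts = chem_io.load_activity_table(config.activities)
    test_ids = chem_io.read_split_file(config.split)
    missing = [m.id for m in mols if m.id not in acts]
    if missing:
        raise ValueError(f"no activity for molecules: {missing}")
    return chem_io.split_dataset(mols, test_ids, activities=acts)


def _ensure_properties(dataset: QsarDataset, method: str) -> QsarDataset:
    out = []
    for m in dataset.molecules:
        if any(a.partial_charge is None for a in m.atoms):
            m = chem_io.assign_gasteiger_charges(m)
        needs_props = method in ("comsia", "both")
        if needs_props and any(
            a.vdw_radius is None or a.hydrophobicity is None
            or a.is_hbd is None or a.is_hba is None
            for a in m.atoms
        ):
            m = chem_io.annotate_properties(m)
        out.append(m)
    return dataset.with_molecules(out)


def _field_blocks(
    dataset: QsarDataset, grid: fields.GridSpec, config: RunConfig
) -> list[fields.FieldBlock]:
    blocks: list[fields.FieldBlock] = []
    if config.method in ("comfa", "both"):
        blocks.extend(fields.comfa_blocks(dataset.molecules, grid))
    if config.method in ("comsia", "both"):
        for kind in config.comsia_kinds:
            blocks.append(fields.comsia_block(dataset.molecules, grid, kind))
    return blocks


def prepare_descriptors(
    config: RunConfig, dataset: QsarDataset | None = None
) -> dict:
    """Align, grid, compute and filter the descriptor matrix.

    Returns a working context (aligned dataset, grid, X, metadata,
    masks) shared by :func:`run_qsar` and the combination sweep.
    """
    t0 = time.perf_counter()
    if dataset is None:
        dataset = _load_dataset(config)
    dataset = _ensure_properties(dataset, config.method)
    template = config.template_id
    if template is None:
        template = max(dataset.train, key=lambda m: m.pic50).id
    aligned, rmsds = align_dataset(dataset, template, config.anchor)
    logger.info("aligned %d molecules to %s (max anchor RMSD %.3f Å)",
                len(rmsds), template, max(rmsds.values()))
    grid = fields.build_grid(aligned.molecules, config.spacing, config.margin)
    logger.info("grid %s points, spacing %.1f Å", grid.dims, grid.spacing)
    blocks = _field_blocks(aligned, grid, config)
    X, metadata = fields.assemble_descriptor_matrix(blocks)
    train_mask = aligned.train_mask()
    Xf, meta_f, keep = fields.filter_columns(X, metadata, config.min_sigma, train_mask)
    logger.info("descriptors: %d columns, %d retained after min_sigma=%g (%.1f s)",
                X.shape[1], Xf.shape[1], config.min_sigma, time.perf_counter() - t0)
    return {
        "dataset": aligned,
        "template_id": template,
        "alignment_rmsd": rmsds,
        "grid": grid,
        "blocks": blocks,
        "X": Xf,
        "metadata": meta_f,
        "train_mask": train_mask,
    }


def _fit_and_validate(ctx: dict, config: RunConfig, max_pcs: int | None = None) -> dict:
    """Model selection, fit and the full statistic battery on a context."""
    X, metadata = ctx["X"], ctx["metadata"]
    train_mask = ctx["train_mask"]
    dataset: QsarDataset = ctx["dataset"]
    X_train, X_test = X[train_mask], X[~train_mask]
    y_train, y_test = dataset.y_train, dataset.y_test
    block_ids = fields.block_labels(metadata)

    pcs, profile = pls_model.select_components(
        X_train, y_train, max_pcs or config.max_pcs, block_ids, config.scaling
    )
    q2, press = pls_model.loo_q2(X_train, y_train, pcs, block_ids, config.scaling)
    model = pls_model.fit_pls(X_train, y_train, pcs, block_ids, config.scaling, metadata)
    stats = pls_model.internal_stats(model, X_train, y_train)
    stats.q2, stats.press = q2, press
    stats.field_contributions = pls_model.field_contributions(
        model, X_train, metadata
    )
    return {
        "model": model,
        "pcs": pcs,
        "q2_profile": profile,
        "stats": stats,
        "X_train": X_train,
        "X_test": X_test,
        "y_train": y_train,
        "y_test": y_test,
        "block_ids": block_ids,
    }


def run_qsar(config: RunConfig, dataset: QsarDataset | None = None) -> dict:
    """Execute the full pipeline and return a JSON-serialisable report.

    When ``config.out_dir`` is set, also writes ``report.json``, the
    internal/external statistics CSVs, the per-molecule alignment
    report and one OpenDX contour file per field kind.
    """
    ctx = prepare_descriptors(config, dataset)
    fit = _fit_and_validate(ctx, config)
    model, stats = fit["model"], fit["stats"]
    X_train, y_train = fit["X_train"], fit["y_train"]

    bs = validation.bootstrap(
        X_train, y_train, fit["pcs"], config.n_bootstrap,
        seed=config.seed, block_ids=fit["block_ids"], scaling=config.scaling,
    )
    stats.r_bs2, stats.see_bs = bs.r_bs2, bs.see_bs
    rand = validation.y_randomization(
        X_train, y_train, fit["pcs"], config.n_randomization,
        seed=config.seed + 1, block_ids=fit["block_ids"], scaling=config.scaling,
    )
    y_pred_test = model.predict(fit["X_test"])
    ext = validation.external_stats(fit["y_test"], y_pred_test, float(y_train.mean()))

    kinds = sorted({m.kind for m in ctx["metadata"]})
    contour_sets = {
        kind: make_contour_set(
            model, X_train, ctx["metadata"], kind, ctx["grid"],
            config.favored_pct, config.disfavored_pct,
        )
        for kind in kinds
    }

    report = {
        "config": _config_dict(config),
        "template_id": ctx["template_id"],
        "alignment_rmsd": {k: round(v, 6) for k, v in ctx["alignment_rmsd"].items()},
        "grid": {"origin": list(ctx["grid"].origin), "spacing": ctx["grid"].spacing,
                 "dims": list(ctx["grid"].dims)},
        "n_train": int(len(y_train)),
        "n_test": int(len(fit["y_test"])),
        "n_columns": int(fit["X_train"].shape[1]),
        "selected_pcs": fit["pcs"],
        "q2_profile": [round(q, 6) for q in fit["q2_profile"]],
        "internal": {
            "q2": stats.q2, "pcs": stats.pcs, "r_ncv2": stats.r_ncv2,
            "see": stats.see, "f_value": stats.f_value,
            "r_bs2": stats.r_bs2, "see_bs": stats.see_bs,
            "press": stats.press,
            "contributions": stats.field_contributions,
        },
        "external": {
            "r_test2": ext.r_test2, "r_pred2": ext.r_pred2, "r0_2": ext.r0_2,
            "r0_2_prime": ext.r0_2_prime, "ratio": ext.ratio, "rm2": ext.rm2,
            "k": ext.k, "k_prime": ext.k_prime,
        },
        "criteria": ext.criteria,
        "y_randomization": {
            "n_runs": rand.n_runs, "q2_min": rand.q2_min, "q2_max": rand.q2_max,
            "q2_values": [round(q, 6) for q in rand.q2_values],
        },
        "contour_levels": {
            k: {"favored": cs.favored_level, "disfavored": cs.disfavored_level}
            for k, cs in contour_sets.items()
        },
    }

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        _internal_table(report).to_csv(out / "internal_stats.csv", index=False)
        _external_table(report).to_csv(out / "external_stats.csv", index=False)
        pd.DataFrame(
            {"id": list(ctx["alignment_rmsd"]), "anchor_rmsd": list(ctx["alignment_rmsd"].values())}
        ).to_csv(out / "alignment_rmsd.csv", index=False)
        for kind, cs in contour_sets.items():
            export_dx(cs, out / f"contour_{kind}.dx")
    return report


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    d["comsia_kinds"] = list(d["comsia_kinds"])
    return d


def _internal_table(report: dict) -> pd.DataFrame:
    """Internal statistics in the conventional one-row table shape."""
    i = report["internal"]
    row = {"q2": i["q2"], "PCs": i["pcs"], "r_ncv2": i["r_ncv2"], "SEE": i["see"],
           "F": i["f_value"], "r_bs2": i["r_bs2"], "SEE_bs": i["see_bs"],
           "r_pred2": report["external"]["r_pred2"]}
    for kind, frac in i["contributions"].items():
        row[f"contrib_{kind}"] = frac
    return pd.DataFrame([row])


def _external_table(report: dict) -> pd.DataFrame:
    e = report["external"]
    return pd.DataFrame(
        [{c: e[c] for c in ("r_test2", "r_pred2", "r0_2", "ratio", "rm2", "k", "k_prime")}]
    )


def field_combination_sweep(
    config: RunConfig, dataset: QsarDataset | None = None, max_pcs: int | None = None
) -> pd.DataFrame:
    """Fit one CoMSIA model per non-empty field subset, ranked by q².

    With the full five fields this enumerates all 2⁵ − 1 = 31
    combinations. Fields are computed once and subset column-wise.
    Returns a table (subset, n_fields, pcs, q2) sorted by q²
    descending, with the winner's field contributions attached to the
    first row.
    """
    if config.method != "comsia":
        raise ValueError("the field-combination sweep is defined for method='comsia'")
    ctx = prepare_descriptors(config, dataset)
    metadata = ctx["metadata"]
    labels = np.array([m.kind for m in metadata])
    kinds = list(config.comsia_kinds)
    rows = []
    best = None
    for r in range(1, len(kinds) + 1):
        for subset in itertools.combinations(kinds, r):
            cols = np.isin(labels, subset)
            sub_ctx = dict(ctx)
            sub_ctx["X"] = ctx["X"][:, cols]
            sub_ctx["metadata"] = [m for m, k in zip(metadata, cols) if k]
            fit = _fit_and_validate(sub_ctx, config, max_pcs=max_pcs)
            q2 = fit["stats"].q2
            rows.append({"subset": "+".join(subset), "n_fields": r,
                         "pcs": fit["pcs"], "q2": q2})
            if best is None or q2 > best[0]:
                best = (q2, rows[-1]["subset"], fit)
    df = pd.DataFrame(rows).sort_values("q2", ascending=False).reset_index(drop=True)
    df["best"] = df["subset"] == best[1]
    contribs = pls_model.field_contributions(
        best[2]["model"], best[2]["X_train"], best[2]["model"].metadata
    )
    df.attrs["winner_contributions"] = contribs
    logger.info("sweep: %d models, best subset %s (q2=%.3f)", len(df), best[1], best[0])
    return df
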