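"""End-to-end orchestration: dock → HH-weight → BML train → redock → PPM/consensus → metrics.

The pipeline mirrors the production workflow shape: every compound (in one
or two ionization states) is docked at each site under unit weights; if
configured, FragMap weights are trained by MCSA on the training split only
and all compounds are redocked under the fixed weights; a physicochemical
MLR and a consensus model are fit on the training split; and a metrics
table (MUE / R / PI / PC) is emitted per model family × site × evaluation
split, with full seed/config provenance.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .bml import AtomicGFETable, BMLConfig, mcsa_optimize
from .docking import DockProtocol, DockResult, dock
from .grids import read_fragmap_set
from .ligands import ClassificationScheme, Ligand, classify_atoms, read_sdf
from .metrics import evaluate
from .ppm import build_feature_matrix, fit_mlr, predict
from .scoring import WeightVector, hh_weighted_lgfe, lgfe_to_pic50

logger = logging.getLogger(__name__)


@dataclass
class Site:
    label: str
    center: tuple[float, float, float]


@dataclass
class RunConfig:
    """Pipeline inputs and knobs; see module docstring for the flow."""

    maps_dir: str
    sdf: str
    affinity_csv: str
    descriptor_csv: str | None = None
    pka_csv: str | None = None
    sites: list[Site] = field(default_factory=lambda: [Site("S1", (0.0, 0.0, 0.0))])
    protocol: DockProtocol = field(default_factory=DockProtocol)
    bml: BMLConfig | None = None
    train_ids: list[str] | None = None  # None → every compound is training
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        labels = [s.label for s in self.sites]
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate site labels: {labels}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        sites = [Site(s["label"], tuple(s["center"])) for s in data.pop("sites", [])]
        protocol = DockProtocol(**data.pop("protocol", {}))
        bml = data.pop("bml", None)
        bml_cfg = BMLConfig(**bml) if bml is not None else None
        cfg = cls(sites=sites or None or [Site("S1", (0.0, 0.0, 0.0))],
                  protocol=protocol, bml=bml_cfg, **data)
        return cfg


def _dock_seed(base: int, site_idx: int, record_idx: int) -> int:
    return int((base * 1_000_003 + site_idx * 10_007 + record_idx * 101 + 7) % (2**31 - 1))


def _round_floats(obj, ndigits: int = 10):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow; returns (and optionally writes) the report.

    Per-ligand docking failures are logged and excluded with a count in the
    report; more than 50% failures aborts the run.
    """
    maps = read_fragmap_set(config.maps_dir)
    ligands = {lig.name: lig for lig in read_sdf(config.sdf)}
    scheme = ClassificationScheme()
    assignments = {name: classify_atoms(lig, scheme) for name, lig in ligands.items()}

    affin = pd.read_csv(config.affinity_csv)
    exp_pic50 = dict(zip(affin["compound"].astype(str), affin["exp_pic50"].astype(float)))

    # compound → records: single-state by default, two-state via the pKa table
    pairs: dict[str, dict] = {}
    if config.pka_csv:
        pka = pd.read_csv(config.pka_csv)
        for _, row in pka.iterrows():
            pairs[str(row["compound"])] = {
                "neutral": str(row["neutral_record"]),
                "charged": str(row["charged_record"]),
                "pKa": float(row["pKa"]),
                "kind": str(row["kind"]),
            }
    compounds = sorted(exp_pic50)
    missing = [c for c in compounds
               for rec in _records_of(c, pairs) if rec not in ligands]
    if missing:
        raise ValueError(f"affinity table references records absent from the SDF: {missing}")

    record_list = sorted({rec for c in compounds for rec in _records_of(c, pairs)})

    def dock_all(w: WeightVector | None, tag: str) -> dict[str, dict[str, DockResult]]:
        """site label → record → DockResult; failures skipped with a log."""
        out: dict[str, dict[str, DockResult]] = {}
        n_fail = 0
        for s_idx, site in enumerate(config.sites):
            out[site.label] = {}
            for r_idx, rec in enumerate(record_list):
                proto = replace(
                    config.protocol,
                    pocket_center=np.asarray(site.center, dtype=float),
                    rng_seed=_dock_seed(config.seed, s_idx, r_idx),
                )
                try:
                    out[site.label][rec] = dock(
                        ligands[rec], maps, assignments[rec], proto,
                        w, site_label=site.label,
                    )
                except Exception as exc:  # noqa: BLE001 — per-ligand skip contract
                    logger.warning("[%s] dock failed for %s at %s: %s", tag, rec, site.label, exc)
                    n_fail += 1
        total = len(record_list) * len(config.sites)
        if total and n_fail > total / 2:
            raise RuntimeError(f"{n_fail}/{total} docking attempts failed; aborting")
        return out

    results_unit = dock_all(None, "unit-weights")

    train_ids = sorted(config.train_ids) if config.train_ids is not None else list(compounds)
    valid_ids = [c for c in compounds if c not in set(train_ids)]

    # --- optional BML training on the first site, training split only -----
    weights: WeightVector | None = None
    results_final = results_unit
    if config.bml is not None:
        first_site = config.sites[0].label
        train_results = {
            c: results_unit[first_site][_records_of(c, pairs)[0]]
            for c in train_ids
            if _records_of(c, pairs)[0] in results_unit[first_site]
        }
        table = AtomicGFETable.from_dock_results(
            train_results, {c: exp_pic50[c] for c in train_results}, maps.map_types
        )
        weights = mcsa_optimize(table, config.bml)
        results_final = dock_all(weights, "bml-weights")

    # --- per-compound structure-based scores ------------------------------
    def compound_scores(site_label: str) -> dict[str, dict[str, float]]:
        scores: dict[str, dict[str, float]] = {}
        res = results_final[site_label]
        for c in compounds:
            recs = _records_of(c, pairs)
            if any(r not in res for r in recs):
                continue
            entry: dict[str, float] = {}
            if c in pairs:
                ln = res[pairs[c]["neutral"]].best_lgfe
                lc = res[pairs[c]["charged"]].best_lgfe
                entry["lgfe_neutral"] = ln
                entry["lgfe_charged"] = lc
                entry["lgfe_hh"] = hh_weighted_lgfe(
                    ln, lc, pairs[c]["pKa"], 7.4, pairs[c]["kind"]
                )
            else:
                entry["lgfe_neutral"] = res[recs[0]].best_lgfe
                entry["lgfe_hh"] = entry["lgfe_neutral"]
            entry["pic50"] = lgfe_to_pic50(entry["lgfe_hh"])
            scores[c] = entry
        return scores

    all_scores = {site.label: compound_scores(site.label) for site in config.sites}

    # --- model families ----------------------------------------------------
    descriptors = None
    if config.descriptor_csv:
        descriptors = pd.read_csv(config.descriptor_csv)

    report_metrics: dict[str, dict] = {}

    def add_metrics(family: str, site: str, split: str, ids: list[str], preds: dict[str, float]):
        usable = [c for c in ids if c in preds]
        if len(usable) < 3:
            return
        rep = evaluate(
            np.array([preds[c] for c in usable]),
            np.array([exp_pic50[c] for c in usable]),
        )
        report_metrics.setdefault(family, {}).setdefault(site, {})[split] = rep.to_dict()

    splits = [("train", train_ids)] + ([("validation", valid_ids)] if valid_ids else [])

    for site in config.sites:
        sl = site.label
        dock_pred = {c: s["pic50"] for c, s in all_scores[sl].items()}
        for split_name, ids in splits:
            add_metrics("docking", sl, split_name, ids, dock_pred)

        if descriptors is not None:
            desc_idx = descriptors.set_index(descriptors["compound"].astype(str))
            have_desc = [c for c in compounds if c in desc_idx.index]

            def fit_family(mode: str, family: str) -> None:
                tr = [c for c in train_ids if c in have_desc and (mode == "ppm_only" or c in dock_pred)]
                X_all = build_feature_matrix(
                    desc_idx.loc[[c for c in have_desc if mode == "ppm_only" or c in dock_pred]],
                    silcs_pic50=dock_pred if mode == "consensus" else None,
                    mode=mode,
                )
                if len(tr) < X_all.shape[1] + 2:
                    return
                model = fit_mlr(X_all.loc[tr], np.array([exp_pic50[c] for c in tr]))
                preds = dict(zip(X_all.index, predict(model, X_all)))
                for split_name, ids in splits:
                    add_metrics(family, sl, split_name, ids, preds)

            fit_family("ppm_only", "ppm")
            fit_family("consensus", "consensus")

    report = {
        "metrics": report_metrics,
        "scores": _round_floats({s: {c: dict(v) for c, v in sc.items()}
                                 for s, sc in all_scores.items()}),
        "bml_weights": ({k: float(v) for k, v in weights.items()} if weights else None),
        "train_ids": train_ids,
        "validation_ids": valid_ids,
        "provenance": {
            "seed": config.seed,
            "package_version": _pkg_version,
            "protocol": _protocol_dict(config.protocol),
            "bml": dataclasses.asdict(config.bml) if config.bml else None,
            "sites": [{"label": s.label, "center": list(s.center)} for s in config.sites],
        },
    }
    report = _round_floats(report)

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "metrics.json").write_text(json.dumps(report["metrics"], indent=2, sort_keys=True))
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        rows = []
        for family, by_site in report_metrics.items():
            for sl, by_split in by_site.items():
                for split, m in by_split.items():
                    rows.append({"family": family, "site": sl, "split": split, **m})
        pd.DataFrame(rows).to_csv(out / "metrics.csv", index=False)
        score_rows = []
        for sl, sc in all_scores.items():
            for c, v in sc.items():
                score_rows.append({"site": sl, "compound": c, **v, "exp_pic50": exp_pic50[c]})
        pd.DataFrame(score_rows).to_csv(out / "scores.csv", index=False)
    return report


def _records_of(compound: str, pairs: dict[str, dict]) -> list[str]:
    if compound in pairs:
        return [pairs[compound]["neutral"], pairs[compound]["charged"]]
    return [compound]


def _protocol_dict(p: DockProtocol) -> dict:
    d = dataclasses.asdict(p)
    d["pocket_center"] = [float(v) for v in p.pocket_center]
    return d


# ---------------------------------------------------------------------------
# Fixture emission (make-fixtures)
# ---------------------------------------------------------------------------

def write_fixture_study(out_dir, spec=None, seed: int = 0, n_ligands: int = 20,
                        protocol: DockProtocol | None = None,
                        alpha: float = 0.5, beta: float = 0.5) -> dict:
    """Write a complete synthetic study (maps, SDF, affinity, descriptors).

    Affinities mix a structure signal (true-weight LGFE of a unit-weight
    docked pose, scaled by ``beta``) and a descriptor signal (``alpha``),
    so all three model families are informative; ``alpha=0, beta=1`` gives
    a purely structure-generated study. Returns paths and ground truth.
    """
    from .ligands import write_sdf
    from .grids import write_fragmap_set
    from .synthetic import (SyntheticSpec, make_descriptor_table, make_fragmaps,
                            make_ligand_set, two_signal_affinities)

    from .synthetic import GaussianWell

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if spec is None:
        # one broad shared basin per type: every pose settles in the same
        # basin regardless of weights, so composition (not pose competition)
        # carries the affinity signal and LGFE stays near-linear in the
        # weights; broad wells also let flexible chains converge quickly
        wells = {
            t: [GaussianWell((0.0, 0.0, 0.0), -6.0, 6.0)]
            for t in ("GENN", "GEND", "GENA", "MAMN", "ACEO")
        }
        spec = SyntheticSpec(n_ligands=n_ligands, rng_seed=seed, wells=wells,
                             size_range=(5, 9))
    rng = np.random.default_rng(seed)
    maps = make_fragmaps(spec)
    maps_dir = out / "maps"
    write_fragmap_set(maps, maps_dir)
    ligset = make_ligand_set(spec, rng)
    write_sdf([lig for lig, _ in ligset], out / "ligands.sdf")

    protocol = protocol or DockProtocol(
        n_min_steps=50, n_mc_steps=300, n_anneal_steps=1200,
        n_independent=2, runs_per_block=2, rng_seed=seed,
    )
    # the structure signal comes from poses docked UNDER the true weights,
    # so unit weights are mis-specified in both the score and the poses
    w_star = WeightVector(spec.true_weights)
    ids, struct_pic50 = [], []
    for idx, (lig, assignment) in enumerate(ligset):
        proto = replace(protocol, rng_seed=_dock_seed(seed, 0, idx))
        res = dock(lig, maps, assignment, proto, w_star)
        ids.append(lig.name)
        struct_pic50.append(lgfe_to_pic50(res.best_lgfe))

    descriptors = make_descriptor_table(ids, rng)
    exp = two_signal_affinities(np.array(struct_pic50), descriptors, spec, rng,
                                alpha=alpha, beta=beta)
    pd.DataFrame({"compound": ids, "exp_pic50": exp}).to_csv(out / "affinity.csv", index=False)
    descriptors.to_csv(out / "descriptors.csv", index=False)
    return {
        "maps_dir": str(maps_dir),
        "sdf": str(out / "ligands.sdf"),
        "affinity_csv": str(out / "affinity.csv"),
        "descriptor_csv": str(out / "descriptors.csv"),
        "true_weights": dict(spec.true_weights),
    }
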