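"""Assessment-report assembly: the end-to-end analysis for one query.

``assess`` runs, for each scenario of a config, the full pipeline —
ensemble (simulated or loaded from PDB files), PB assignment, per-position
frequency/Neq statistics, best-model selection by external score, global and
region-wise RMSD, CDR loop-termini distances and Ramachandran fractions —
and writes a JSON report plus per-position CSV/TSV tables.  ``compare``
re-reads two or more scenario blocks and tabulates per-position Delta-Neq
and Delta-PB for every scenario pair.

All numbers in a report are recomputable: the report stores the input file
paths or the simulation spec (including seeds), and nothing is written until
every stage has finished, so partial reports never appear on disk.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ensemble_stats as es
from . import pb_alphabet as pba
from . import structure_io as sio
from . import superpose_metrics as sm
from . import synthetic_data as syn
from . import template_select as ts
from .vhh_regions import RegionMap

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1


class StageError(RuntimeError):
    """Pipeline failure tagged with the stage that raised it."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _load_models_from_dir(models_dir, chain_id, scores_path):
    mdir = Path(models_dir)
    if not mdir.is_dir():
        raise StageError("load_models", f"missing model directory {mdir}")
    scores = pd.read_csv(scores_path)
    models, ids = [], []
    for _, row in scores.iterrows():
        models.append(sio.read_pdb_chain(mdir / f"{row.model_id}.pdb", chain_id))
        ids.append(row.model_id)
    return models, scores


def _scenario_ensemble(block: dict, native: sio.BackboneChain, seed: int, table):
    """Build (models, scores) for one scenario block of the config."""
    if "models_dir" in block:
        return _load_models_from_dir(
            block["models_dir"], block.get("chain_id", "A"), block["scores"])
    kappa = block.get("kappa", {})
    default_kappa = float(kappa.get("default", 500.0))
    profile = np.full(len(native), default_kappa)
    for name, value in kappa.items():
        if name == "default":
            continue
        start, end = block["regions"][name]
        profile[start - 1:end] = float(value)
    anchors = None
    if block.get("anchored", True):
        anchors = [tuple(v) for v in block["regions"].values()]
    spec = syn.EnsembleSpec(
        reference_pb_string=block["reference_pb_string"],
        kappa_profile=profile,
        n_models=int(block.get("n_models", 100)),
        seed=int(block.get("seed", seed)),
        score_noise=float(block.get("score_noise", 5.0)),
        sequence=block.get("sequence"),
        anchor_segments=anchors,
    )
    models, scores = syn.generate_ensemble(spec, table)
    return models, scores


def assess(config: dict, out_dir) -> dict:
    """Run the full assessment for one query; returns the report dict.

    See the CLI documentation for the config schema.  Everything is computed
    in memory first; files are written only after all stages succeed.
    """
    t0 = time.time()
    table = pba.load_reference_table()
    seed = int(config.get("seed", 0))
    query_id = config.get("query_id", "query")

    # --- native structure ---------------------------------------------
    nat = config.get("native", {})
    try:
        if "pdb" in nat:
            native = sio.read_pdb_chain(nat["pdb"], nat.get("chain", "A"))
        elif "pb_string" in nat:
            native = syn.reference_chain(
                syn.EnsembleSpec(nat["pb_string"],
                                 np.ones(len(nat["pb_string"])),
                                 sequence=nat.get("sequence")),
                table)
        else:
            raise ValueError("config.native needs 'pdb' or 'pb_string'")
    except StageError:
        raise
    except Exception as exc:
        raise StageError("native", str(exc))

    try:
        regions = RegionMap({k: tuple(v) for k, v in config["regions"].items()})
        if regions.length != len(native):
            raise ValueError(
                f"region map covers 1..{regions.length}, native has {len(native)}")
    except StageError:
        raise
    except Exception as exc:
        raise StageError("regions", str(exc))

    native_dih = sio.compute_backbone_dihedrals(native)
    native_pb = pba.assign_pb_sequence(native_dih, table)

    report = {
        "schema_version": SCHEMA_VERSION,
        "query_id": query_id,
        "config_hash": _config_hash(config),
        "seed": seed,
        "length": len(native),
        "regions": {k: list(v) for k, v in regions.items()},
        "native": {
            "pb_string": native_pb,
            "cdr_termini_distance": {
                name: sm.loop_termini_distance(native, regions[name])
                for name in regions.cdr_names()
            },
        },
        "scenarios": {},
    }

    tables = {}  # files to write at the end
    for block in config["scenarios"]:
        name = block["name"]
        logger.info("stage scenario=%s start", name)
        t1 = time.time()
        try:
            block = dict(block)
            block.setdefault("regions", {k: list(v) for k, v in regions.items()})
            models, scores = _scenario_ensemble(block, native, seed, table)
        except StageError:
            raise
        except Exception as exc:
            raise StageError(f"ensemble:{name}", str(exc))

        try:
            pb_strings = [
                pba.assign_pb_sequence(sio.compute_backbone_dihedrals(m), table)
                for m in models
            ]
            profile = es.pb_frequency_profile(pb_strings)
            neq = es.neq_profile(profile)

            score_map = dict(zip(scores.model_id, scores.score))
            best_id = ts.select_best_model(score_map)
            best = models[list(scores.model_id).index(best_id)]
            best_dih = sio.compute_backbone_dihedrals(best)

            global_rmsd = sm.superpose_calpha(best, native).rmsd
            per_region = {
                mode: sm.region_rmsd(best, native, regions, mode=mode)
                for mode in ("local_fit", "frame_fit")
            }
            termini = {
                rn: sm.loop_termini_distance(best, regions[rn])
                for rn in regions.cdr_names()
            }
            rama = sm.ramachandran_fractions(best_dih)
            best_pb = pba.assign_pb_sequence(best_dih, table)
        except StageError:
            raise
        except Exception as exc:
            raise StageError(f"assess:{name}", str(exc))

        report["scenarios"][name] = {
            "n_models": len(models),
            "best_model_id": best_id,
            "best_model_global_rmsd": global_rmsd,
            "region_rmsd": per_region,
            "cdr_termini_distance": termini,
            "best_model_pb_string": best_pb,
            "ramachandran": rama,
            "mismatches_vs_native": pba.pb_mismatch_count(best_pb, native_pb),
        }
        tables[f"pb_map_{name}.tsv"] = es.pb_map(profile, as_frequency=False)
        stats = pd.DataFrame({
            "position": np.arange(1, len(native) + 1),
            "neq": neq,
            "support": profile.support_count,
        })
        tables[f"positions_{name}.csv"] = stats
        tables[f"scores_{name}.csv"] = scores
        logger.info("stage scenario=%s done in %.2fs", name, time.time() - t1)

    # --- write everything atomically-ish ------------------------------
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for fname, df in tables.items():
        if fname.endswith(".tsv"):
            df.to_csv(out / fname, sep="\t")
        else:
            df.to_csv(out / fname, index=False)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    logger.info("assessment complete in %.2fs", time.time() - t0)
    return report


def load_scenario_profile(report_dir, scenario: str) -> es.PBFrequencyProfile:
    df = es.read_pb_map(Path(report_dir) / f"pb_map_{scenario}.tsv")
    return es.profile_from_pb_map_counts(df)


def compare(report_dirs, scenarios=None) -> dict:
    """Pairwise Delta-Neq / Delta-PB tables across scenario blocks.

    ``report_dirs`` maps a label to an assess output directory; if
    ``scenarios`` is None every scenario found in each report is used.
    Returns {(label_a, label_b): DataFrame} with per-position columns
    delta_neq and delta_pb, plus a 'flagged' summary of positions where
    delta_pb > 1 (conformations mostly disjoint between the two runs).
    """
    profiles = {}
    for label, rdir in report_dirs.items():
        with open(Path(rdir) / "report.json") as fh:
            rep = json.load(fh)
        names = scenarios or list(rep["scenarios"])
        for name in names:
            profiles[f"{label}:{name}"] = load_scenario_profile(rdir, name)

    keys = list(profiles)
    out = {}
    for i, a in enumerate(keys):
        for b in keys[i + 1:]:
            pa, pb_ = profiles[a], profiles[b]
            if len(pa) != len(pb_):
                raise ValueError(f"length mismatch between {a} and {b}")
            dneq = es.delta_neq(pa, pb_)
            dpb = es.delta_pb(pa, pb_)
            df = pd.DataFrame({
                "position": np.arange(1, len(pa) + 1),
                "delta_neq": dneq,
                "delta_pb": dpb,
            })
            df["flagged"] = df.delta_pb > 1.0
            out[(a, b)] = df
    return out


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
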