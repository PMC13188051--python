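"""Batch profiling: apply every registry model to every target chemical.

`profile` produces the full cross product of targets × models as tidy
pandas tables — one prediction row per pair, plus an AD-details table with
the numeric evidence behind every verdict and a neighbor table per
(target, model).  Inapplicable pairs are never dropped: they get a row with
a machine-readable skip reason.  Profiling is a pure function of its inputs,
so repeated runs export byte-identical files.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Optional, Sequence

import pandas as pd

from .base import QsarError
from .chemistry import (
    ChemicalStructure,
    SmilesParseError,
    compute_fingerprint,
    parse_smiles,
    resolve_descriptor_vector,
)
from .consensus import combine
from .lda import LdaModel, predict_lda
from .mlr import MlrModel, prediction_interval
from .neighbors import find_neighbors

logger = logging.getLogger("qsarprofiler.profiler")

__all__ = [
    "Target",
    "ProfileOptions",
    "ProfileResult",
    "profile",
    "expand_metabolites",
    "export_report",
    "EXPORT_FORMATS",
]

EXPORT_FORMATS = ("csv", "xlsx")


@dataclass(frozen=True)
class Target:
    """A chemical to be profiled: id plus SMILES and/or supplied descriptors."""

    id: str
    smiles: Optional[str] = None
    supplied: Optional[Mapping[str, float]] = None
    parent_id: Optional[str] = None


@dataclass(frozen=True)
class ProfileOptions:
    alpha: float = 0.05
    neighbors_k: int = 5
    fingerprint: str = "hashed_path"
    similarity_index: str = "tanimoto"
    consensus_policy: str = "none"  # none | all | in_ad_only
    strict_and: bool = False


@dataclass
class ProfileResult:
    predictions: pd.DataFrame
    ad_details: pd.DataFrame
    neighbors: pd.DataFrame
    consensus: pd.DataFrame


# MetaboliteHook contract: SMILES -> list of (metabolite SMILES, reaction label).
MetaboliteHook = Callable[[str], Sequence]


def expand_metabolites(targets: Sequence[Target],
                       hook: Optional[MetaboliteHook]) -> list:
    """Append each target's detected metabolites as new targets.

    Metabolite targets carry ``parent_id`` for lineage.  A hook failure
    leaves the parent profiled alone with a logged warning; no hook returns
    the targets unchanged.
    """
    if hook is None:
        return list(targets)
    out = []
    for t in targets:
        out.append(t)
        if not t.smiles:
            continue
        try:
            metabolites = hook(t.smiles)
        except Exception as exc:  # external-process boundary: isolate failures
            logger.warning("metabolite hook failed for %s: %s", t.id, exc)
            warnings.warn(f"metabolite hook failed for target {t.id!r}: {exc}",
                          stacklevel=2)
            continue
        for i, (smi, reaction) in enumerate(metabolites, start=1):
            out.append(Target(id=f"{t.id}__met{i}_{reaction}", smiles=smi,
                              supplied=t.supplied, parent_id=t.id))
    return out


def _parse_targets(targets: Sequence[Target]):
    """Parse each target's SMILES once; return {id: (structure|None, error|None)}."""
    parsed = {}
    for t in targets:
        if t.smiles is None:
            parsed[t.id] = (None, None)
            continue
        try:
            parsed[t.id] = (parse_smiles(t.smiles, id=t.id), None)
        except SmilesParseError as exc:
            parsed[t.id] = (None, str(exc))
    return parsed


def _neighbor_rows(model, structure, target_id, options: ProfileOptions):
    train = [(r.id, r.smiles, r.y) for r in model.training if r.smiles]
    if structure is None or not train:
        return []
    try:
        target_fp = compute_fingerprint(structure, kind=options.fingerprint)
        fps, ids, ys, smis = [], [], [], []
        for tid, smi, y in train:
            st = parse_smiles(smi, id=tid)
            fps.append(compute_fingerprint(st, kind=options.fingerprint))
            ids.append(tid)
            ys.append(y)
            smis.append(st.canonical_smiles)
    except QsarError as exc:
        logger.warning("neighbor analysis failed for %s/%s: %s", target_id,
                       model.metadata.model_id, exc)
        return []
    hits = find_neighbors(target_fp, fps, index=options.similarity_index,
                          k=options.neighbors_k, ids=ids, y=ys)
    by_id = dict(zip(ids, smis))
    return [
        {
            "target_id": target_id,
            "model_id": model.metadata.model_id,
            "rank": h.rank,
            "training_id": h.training_id,
            "canonical_smiles": by_id[h.training_id],
            "similarity": h.similarity,
            "distance": h.distance,
            "experimental_y": h.y,
        }
        for h in hits
    ]


def profile(targets: Sequence[Target], registry,
            options: ProfileOptions = ProfileOptions()) -> ProfileResult:
    """Apply every registry model to every target (deterministic ordering)."""
    if not targets:
        raise QsarError("no targets to profile")
    if len(registry) == 0:
        raise QsarError("registry holds no models")
    parsed = _parse_targets(targets)

    pred_rows, ad_rows, nb_rows, cons_rows = [], [], [], []
    mlr_preds: dict = {}  # (target_id, model_id) -> Prediction, for consensus

    for t in targets:
        structure, parse_err = parsed[t.id]
        for model in registry:
            md = model.metadata
            row = {
                "target_id": t.id,
                "parent_id": t.parent_id or "",
                "model_id": md.model_id,
                "group": md.group,
                "subgroup": md.subgroup,
                "endpoint": md.endpoint_name,
                "units": md.units,
                "model_type": model.model_type,
                "prediction": None,
                "uncertainty": None,
                "uncertainty_kind": "",
                "structural_in_ad": None,
                "endpoint_in_ad": None,
                "in_ad": None,
                "reasons": "",
                "top_neighbor_id": "",
                "top_neighbor_similarity": None,
                "top_neighbor_y": None,
                "skip_reason": "",
                "citation": md.citation,
            }
            if parse_err is not None:
                row["skip_reason"] = parse_err
                pred_rows.append(row)
                continue
            try:
                vec = resolve_descriptor_vector(
                    model.specs, structure=structure, supplied=t.supplied
                )
            except QsarError as exc:
                row["skip_reason"] = str(exc)
                pred_rows.append(row)
                continue

            ad = {"target_id": t.id, "model_id": md.model_id,
                  "model_type": model.model_type}
            if isinstance(model, MlrModel):
                pred = prediction_interval(model, vec.values, alpha=options.alpha,
                                           strict_and=options.strict_and)
                mlr_preds[(t.id, md.model_id)] = pred
                row.update(
                    prediction=pred.value, uncertainty=pred.halfwidth,
                    uncertainty_kind="interval_halfwidth",
                    structural_in_ad=pred.structural_in_ad,
                    endpoint_in_ad=pred.endpoint_in_ad,
                    in_ad=pred.structural_in_ad and pred.endpoint_in_ad,
                    reasons="; ".join(pred.reasons),
                )
                ad.update(
                    leverage=pred.leverage,
                    leverage_cutoff=model.leverage_cutoff,
                    std_residual=pred.endpoint_verdict.details["standardized_residual"],
                    value=pred.value, halfwidth=pred.halfwidth,
                    y_min=model.y_range[0], y_max=model.y_range[1],
                    halfwidth_min=model.halfwidth_range[0],
                    halfwidth_max=model.halfwidth_range[1],
                )
                for name, status in {**pred.structural_verdict.criteria,
                                     **pred.endpoint_verdict.criteria}.items():
                    ad[f"criterion_{name}"] = status.value
            else:
                assert isinstance(model, LdaModel)
                pred = predict_lda(model, vec.values)
                row.update(
                    prediction=str(pred.label), uncertainty=pred.entropy,
                    uncertainty_kind="shannon_entropy_bits",
                    structural_in_ad=pred.structural_in_ad,
                    endpoint_in_ad=pred.endpoint_in_ad,
                    in_ad=pred.structural_in_ad and pred.endpoint_in_ad,
                    reasons="; ".join(pred.reasons),
                )
                ad.update(
                    similarity=pred.similarity,
                    similarity_cutoff=model.sim_cutoff,
                    posterior=max(pred.posteriors.values()),
                )
                for name, status in {**pred.structural_verdict.criteria,
                                     **pred.endpoint_verdict.criteria}.items():
                    ad[f"criterion_{name}"] = status.value
            ad_rows.append(ad)

            hits = _neighbor_rows(model, structure, t.id, options)
            nb_rows.extend(hits)
            if hits:
                row["top_neighbor_id"] = hits[0]["training_id"]
                row["top_neighbor_similarity"] = hits[0]["similarity"]
                row["top_neighbor_y"] = hits[0]["experimental_y"]
            pred_rows.append(row)

        if options.consensus_policy != "none":
            cons_rows.extend(
                _consensus_rows(t, registry, mlr_preds, options.consensus_policy)
            )

    return ProfileResult(
        predictions=pd.DataFrame(pred_rows),
        ad_details=pd.DataFrame(ad_rows),
        neighbors=pd.DataFrame(nb_rows),
        consensus=pd.DataFrame(cons_rows),
    )


def _consensus_rows(target: Target, registry, mlr_preds, policy: str):
    rows = []
    for (group, subgroup), models in registry.groups().items():
        members, ids, flags, excluded = [], [], [], []
        for model in models:
            mid = model.metadata.model_id
            if not isinstance(model, MlrModel):
                excluded.append((mid, "not a regression model"))
                continue
            pred = mlr_preds.get((target.id, mid))
            if pred is None:
                excluded.append((mid, "no prediction (skipped)"))
                continue
            in_ad = pred.structural_in_ad and pred.endpoint_in_ad
            if policy == "in_ad_only" and not in_ad:
                excluded.append((mid, "out of applicability domain"))
                continue
            if pred.halfwidth <= 0.0:
                excluded.append((mid, "degenerate zero-uncertainty prediction"))
                continue
            members.append((pred.value, pred.halfwidth))
            ids.append(mid)
            flags.append(in_ad)
        if not members:
            continue
        res = combine(members, model_ids=ids, in_ad=flags, excluded=excluded)
        rows.append({
            "target_id": target.id,
            "group": group,
            "subgroup": subgroup,
            "policy": policy,
            "n_members": len(res.members),
            "members": "; ".join(m.model_id for m in res.members),
            "value": res.value,
            "uncertainty": res.uncertainty,
            "excluded": "; ".join(f"{mid}: {why}" for mid, why in res.excluded),
        })
    return rows


_SHEETS = ("predictions", "consensus", "neighbors", "ad_details")


def export_report(result: ProfileResult, outdir, format: str = "csv") -> list:
    """Export the four report tables (QPRF-oriented columns).

    ``csv`` writes one file per table (canonical, byte-exact across reruns);
    ``xlsx`` writes one workbook with four sheets.  Returns written paths.
    """
    if format not in EXPORT_FORMATS:
        raise QsarError(
            f"unsupported export format {format!r}; supported: {EXPORT_FORMATS}"
        )
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tables = {
        "predictions": result.predictions,
        "consensus": result.consensus,
        "neighbors": result.neighbors,
        "ad_details": result.ad_details,
    }
    written = []
    if format == "csv":
        for name in _SHEETS:
            path = outdir / f"{name}.csv"
            tables[name].to_csv(path, index=False)
            written.append(path)
    else:
        path = outdir / "report.xlsx"
        with pd.ExcelWriter(path, engine="openpyxl") as writer:
            for name in _SHEETS:
                df = tables[name]
                if df.empty:  # openpyxl needs at least a header row
                    df = pd.DataFrame({"empty": []})
                df.to_excel(writer, sheet_name=name, index=False)
        written.append(path)
    return written
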