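"""Model and table I/O.

Two model formats are supported:

* a compact JSON dialect used for fixtures and synthetic models (bit-exact
  round trip), documented below;
* SBML Level 3 + FBC, read and written through cobrapy/libSBML (numeric
  fields preserved to double precision).

JSON dialect::

    {
      "id": "...",
      "metabolites": [{"id", "name", "compartment", "formula", "charge"}...],
      "reactions":   [{"id", "name", "stoichiometry": {met: coeff},
                       "lower_bound", "upper_bound", "gpr", "subsystem"}...],
      "objective": "<reaction id>",
      "ngam": "<reaction id>"          # optional
    }

Media tables are CSV with columns ``reaction_id, lb, ub``.  Growth-condition
tables are long-form CSV with columns ``condition_id, observed_growth,
description, reaction_id, lb, ub`` (condition metadata repeated per row).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Union

import pandas as pd

from .core import (
    Medium,
    MetabolicModel,
    Metabolite,
    ModelError,
    Reaction,
    parse_gpr,
)

PathLike = Union[str, Path]


# ---------------------------------------------------------------------------
# JSON dialect
# ---------------------------------------------------------------------------

def model_to_dict(model: MetabolicModel) -> dict:
    doc = {
        "id": model.id,
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "compartment": m.compartment,
                "formula": m.formula,
                "charge": m.charge,
            }
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "stoichiometry": dict(r.stoichiometry),
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "gpr": r.gpr.to_string(),
                "subsystem": r.subsystem,
            }
            for r in model.reactions
        ],
        "objective": model.objective_reaction_id,
    }
    if model.ngam_reaction_id:
        doc["ngam"] = model.ngam_reaction_id
    return doc


def model_from_dict(doc: dict) -> MetabolicModel:
    for key in ("metabolites", "reactions", "objective"):
        if key not in doc:
            raise ModelError(f"model document missing {key!r}")
    model = MetabolicModel(
        id=doc.get("id", "model"),
        metabolites=[
            Metabolite(
                id=m["id"],
                name=m.get("name", ""),
                compartment=m.get("compartment", "c"),
                formula=m.get("formula", ""),
                charge=int(m.get("charge", 0)),
            )
            for m in doc["metabolites"]
        ],
        reactions=[
            Reaction(
                id=r["id"],
                name=r.get("name", ""),
                stoichiometry={k: float(v) for k, v in r["stoichiometry"].items()},
                lower_bound=float(r["lower_bound"]),
                upper_bound=float(r["upper_bound"]),
                gpr=parse_gpr(r.get("gpr", "")),
                subsystem=r.get("subsystem", ""),
            )
            for r in doc["reactions"]
        ],
        objective_reaction_id=doc["objective"],
        ngam_reaction_id=doc.get("ngam"),
    )
    model.validate()
    return model


# ---------------------------------------------------------------------------
# cobra bridge and SBML
# ---------------------------------------------------------------------------

def to_cobra(model: MetabolicModel):
    """Convert to a :class:`cobra.Model` (used for SBML I/O and cross-checks)."""
    import cobra

    model.validate()
    cm = cobra.Model(model.id)
    mets = {}
    for m in model.metabolites:
        mets[m.id] = cobra.Metabolite(
            m.id,
            name=m.name,
            compartment=m.compartment,
            formula=m.formula or None,
            charge=m.charge,
        )
    cm.add_metabolites(list(mets.values()))
    rxns = []
    for r in model.reactions:
        cr = cobra.Reaction(
            r.id, name=r.name, subsystem=r.subsystem,
            lower_bound=r.lower_bound, upper_bound=r.upper_bound,
        )
        rxns.append(cr)
    cm.add_reactions(rxns)
    for r, cr in zip(model.reactions, rxns):
        cr.add_metabolites({mets[mid]: c for mid, c in r.stoichiometry.items()})
        rule = r.gpr.to_string()
        if rule:
            cr.gene_reaction_rule = rule
    cm.objective = model.objective_reaction_id
    return cm


def write_model(model: MetabolicModel, path: PathLike, format: str = "json") -> None:
    """Write a model as JSON (dialect above) or SBML L3+FBC."""
    path = Path(path)
    if format == "json":
        path.write_text(json.dumps(model_to_dict(model), indent=1))
    elif format in ("sbml", "sbml-fbc"):
        import cobra

        cobra.io.write_sbml_model(to_cobra(model), str(path))
    else:
        raise ValueError(f"unknown model format {format!r}")


def read_model(path: PathLike, format: str = "json") -> MetabolicModel:
    """Read a model from JSON (dialect above) or SBML L3+FBC."""
    path = Path(path)
    if format == "json":
        return model_from_dict(json.loads(path.read_text()))
    if format in ("sbml", "sbml-fbc"):
        import cobra

        cm = cobra.io.read_sbml_model(str(path))
        return from_cobra(cm)
    raise ValueError(f"unknown model format {format!r}")


def from_cobra(cm) -> MetabolicModel:
    """Convert a :class:`cobra.Model` to a :class:`MetabolicModel`."""
    from cobra.util.solver import linear_reaction_coefficients

    objective = linear_reaction_coefficients(cm)
    if not objective:
        raise ModelError(f"model {cm.id!r} has no objective reaction set")
    objective_id = max(objective, key=lambda r: abs(objective[r])).id
    model = MetabolicModel(
        id=cm.id or "model",
        metabolites=[
            Metabolite(
                id=m.id,
                name=m.name or "",
                compartment=m.compartment or "c",
                formula=m.formula or "",
                charge=int(m.charge or 0),
            )
            for m in cm.metabolites
        ],
        reactions=[
            Reaction(
                id=r.id,
                name=r.name or "",
                stoichiometry={m.id: float(c) for m, c in r.metabolites.items()},
                lower_bound=float(r.lower_bound),
                upper_bound=float(r.upper_bound),
                gpr=parse_gpr(r.gene_reaction_rule),
                subsystem=r.subsystem or "",
            )
            for r in cm.reactions
        ],
        objective_reaction_id=objective_id,
    )
    model.validate()
    return model


# ---------------------------------------------------------------------------
# CSV tables
# ---------------------------------------------------------------------------

def read_medium_csv(path: PathLike) -> Medium:
    df = pd.read_csv(path)
    required = {"reaction_id", "lb", "ub"}
    if not required.issubset(df.columns):
        raise ValueError(f"medium CSV needs columns {sorted(required)}")
    return {
        str(row.reaction_id): (float(row.lb), float(row.ub))
        for row in df.itertuples()
    }


def write_medium_csv(medium: Medium, path: PathLike) -> None:
    rows = [
        {"reaction_id": rid, "lb": lb, "ub": ub}
        for rid, (lb, ub) in sorted(medium.items())
    ]
    pd.DataFrame(rows, columns=["reaction_id", "lb", "ub"]).to_csv(path, index=False)


def read_conditions_csv(path: PathLike) -> List["GrowthCondition"]:
    """Read long-form growth-condition tables (see module docstring)."""
    from .validation import GrowthCondition

    df = pd.read_csv(path)
    required = {"condition_id", "observed_growth", "reaction_id", "lb", "ub"}
    if not required.issubset(df.columns):
        raise ValueError(f"conditions CSV needs columns {sorted(required)}")
    conditions = []
    for cond_id, group in df.groupby("condition_id", sort=False):
        medium: Medium = {
            str(row.reaction_id): (float(row.lb), float(row.ub))
            for row in group.itertuples()
        }
        observed = bool(group["observed_growth"].iloc[0])
        description = (
            str(group["description"].iloc[0]) if "description" in group else ""
        )
        conditions.append(
            GrowthCondition(
                condition_id=str(cond_id),
                medium=medium,
                observed_growth=observed,
                description=description,
            )
        )
    return conditions
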