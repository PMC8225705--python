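"""Readers and writers for constraint-based model files.

Two on-disk formats are supported:

* SBML Level 3 Version 1 with the FBC version 2 package (flux bounds as
  referenced parameters, the objective as ``fbc:objective``, GPRs as
  ``fbc:geneProductAssociation``) and the Groups version 1 package for
  subsystem labels — the subset written by the mainstream constraint-based
  tools.
* The community JSON schema for constraint-based models (a ``reactions``
  list with ``lower_bound`` / ``upper_bound`` / ``gene_reaction_rule`` /
  ``subsystem`` entries).

Identifiers are treated as opaque strings.  Because SBML SIds are restricted
to ``[A-Za-z_][A-Za-z0-9_]*``, arbitrary identifiers (including non-ASCII)
are escaped reversibly when written and unescaped when read, so a
write/read round-trip preserves them byte for byte.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Optional, Union

import numpy as np
from lxml import etree

from .gpr import GPR, parse_gpr
from .model import MetabolicModel, build_model

__all__ = ["read_model", "write_model", "ModelFormatError"]

SBML_NS = "http://www.sbml.org/sbml/level3/version1/core"
FBC_NS = "http://www.sbml.org/sbml/level3/version1/fbc/version2"
GROUPS_NS = "http://www.sbml.org/sbml/level3/version1/groups/version1"
NSMAP = {None: SBML_NS, "fbc": FBC_NS, "groups": GROUPS_NS}


class ModelFormatError(ValueError):
    """Raised when a model file cannot be parsed into a valid model."""


# ---------------------------------------------------------------------------
# SId escaping: any character outside [A-Za-z0-9_] becomes __<codepoint>__.
# The escape is its own marker, so decoding is unambiguous.
# ---------------------------------------------------------------------------

_SID_OK = re.compile(r"[A-Za-z0-9_]")
_SID_ESC = re.compile(r"__(\d+)__")


def _encode_sid(identifier: str, prefix: str) -> str:
    out = [prefix]
    for ch in identifier:
        if _SID_OK.fullmatch(ch) and ch != "_":
            out.append(ch)
        elif ch == "_":
            out.append("__95__")
        else:
            out.append(f"__{ord(ch)}__")
    return "".join(out)


def _decode_sid(sid: str, prefix: str) -> str:
    if not sid.startswith(prefix):
        raise ModelFormatError(f"identifier {sid!r} lacks expected prefix {prefix!r}")
    return _SID_ESC.sub(lambda m: chr(int(m.group(1))), sid[len(prefix):])


def _q(ns: str, tag: str) -> str:
    return f"{{{ns}}}{tag}"


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def read_model(path: Union[str, Path], format: Optional[str] = None) -> MetabolicModel:
    """Read a model from SBML (L3+FBC) or community JSON.

    ``format`` is ``"sbml"`` or ``"json"``; inferred from the file suffix
    when omitted.  Missing flux bounds raise — no silent defaults.
    """
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "sbml")
    if fmt == "json":
        return _read_json(path)
    if fmt == "sbml":
        return _read_sbml(path)
    raise ValueError(f"unknown model format {fmt!r}")


def write_model(model: MetabolicModel, path: Union[str, Path],
                format: Optional[str] = None) -> Path:
    """Write a model to SBML or JSON; re-reading yields an equal model."""
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "sbml")
    if fmt == "json":
        _write_json(model, path)
    elif fmt == "sbml":
        _write_sbml(model, path)
    else:
        raise ValueError(f"unknown model format {fmt!r}")
    return path


# ---------------------------------------------------------------------------
# JSON
# ---------------------------------------------------------------------------

def _read_json(path: Path) -> MetabolicModel:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ModelFormatError(f"{path}: not valid JSON ({exc})") from exc
    for key in ("reactions", "metabolites"):
        if key not in doc:
            raise ModelFormatError(f"{path}: missing top-level {key!r} list")
    met_order = [m["id"] for m in doc["metabolites"]]
    reactions = []
    gprs, subsystems, objective = {}, {}, {}
    for rxn in doc["reactions"]:
        rid = rxn.get("id")
        if rid is None:
            raise ModelFormatError(f"{path}: reaction without an id")
        if "lower_bound" not in rxn or "upper_bound" not in rxn:
            raise ModelFormatError(
                f"{path}: reaction {rid!r} lacks explicit flux bounds")
        reactions.append((rid, dict(rxn.get("metabolites", {})),
                          float(rxn["lower_bound"]), float(rxn["upper_bound"])))
        gprs[rid] = rxn.get("gene_reaction_rule", "")
        subsystems[rid] = rxn.get("subsystem", "") or ""
        coef = rxn.get("objective_coefficient", 0.0)
        if coef:
            objective[rid] = float(coef)
    model = build_model(reactions, gprs=gprs, subsystems=subsystems,
                        objective=objective, model_id=doc.get("id", path.stem))
    # honour the file's metabolite ordering (build_model uses first appearance)
    model = _reorder_metabolites(model, met_order, path)
    genes = [g["id"] for g in doc.get("genes", [])]
    if genes:
        _check_gene_cover(model, genes, path)
        model.gene_ids = genes
    return model


def _reorder_metabolites(model: MetabolicModel, met_order: list[str],
                         path: Path) -> MetabolicModel:
    if met_order == model.metabolite_ids:
        return model
    missing = set(model.metabolite_ids) - set(met_order)
    if missing:
        raise ModelFormatError(
            f"{path}: metabolite(s) {sorted(missing)} used in reactions but "
            f"absent from the metabolites list")
    keep = [m for m in met_order if m in set(model.metabolite_ids)]
    idx = {m: i for i, m in enumerate(model.metabolite_ids)}
    perm = [idx[m] for m in keep]
    model.S = model.S[perm, :]
    model.metabolite_ids = keep
    return model


def _check_gene_cover(model: MetabolicModel, genes: list[str], path: Path):
    declared = set(genes)
    for j, g in enumerate(model.gpr_rules):
        if g is None:
            continue
        extra = g.genes() - declared
        if extra:
            raise ModelFormatError(
                f"{path}: reaction {model.reaction_ids[j]!r} references "
                f"undeclared gene(s) {sorted(extra)}")


def _write_json(model: MetabolicModel, path: Path):
    doc = {
        "id": model.model_id,
        "version": "1",
        "metabolites": [{"id": m, "name": m, "compartment": ""}
                        for m in model.metabolite_ids],
        "genes": [{"id": g, "name": g} for g in model.gene_ids],
        "reactions": [],
    }
    S = model.S.tocsc()
    for j, rid in enumerate(model.reaction_ids):
        col = S.getcol(j).tocoo()
        mets = {model.metabolite_ids[i]: float(v)
                for i, v in zip(col.row, col.data)}
        entry = {
            "id": rid,
            "name": rid,
            "metabolites": mets,
            "lower_bound": float(model.lower_bounds[j]),
            "upper_bound": float(model.upper_bounds[j]),
            "gene_reaction_rule": model.gpr_string(j),
            "subsystem": model.subsystems[j],
        }
        if model.objective_coeffs[j]:
            entry["objective_coefficient"] = float(model.objective_coeffs[j])
        doc["reactions"].append(entry)
    Path(path).write_text(json.dumps(doc, indent=1, ensure_ascii=False))


# ---------------------------------------------------------------------------
# SBML
# ---------------------------------------------------------------------------

def _write_sbml(model: MetabolicModel, path: Path):
    root = etree.Element(_q(SBML_NS, "sbml"), nsmap=NSMAP)
    root.set("level", "3")
    root.set("version", "1")
    root.set(_q(FBC_NS, "required"), "false")
    root.set(_q(GROUPS_NS, "required"), "false")
    mnode = etree.SubElement(root, _q(SBML_NS, "model"))
    mnode.set("id", _encode_sid(model.model_id, "MOD_"))
    mnode.set("name", model.model_id)
    mnode.set(_q(FBC_NS, "strict"), "true")

    comps = etree.SubElement(mnode, _q(SBML_NS, "listOfCompartments"))
    comp = etree.SubElement(comps, _q(SBML_NS, "compartment"))
    comp.set("id", "default")
    comp.set("constant", "true")

    species = etree.SubElement(mnode, _q(SBML_NS, "listOfSpecies"))
    for mid in model.metabolite_ids:
        s = etree.SubElement(species, _q(SBML_NS, "species"))
        s.set("id", _encode_sid(mid, "M_"))
        s.set("name", mid)
        s.set("compartment", "default")
        s.set("hasOnlySubstanceUnits", "false")
        s.set("boundaryCondition", "false")
        s.set("constant", "false")

    # one shared parameter per distinct bound value
    bound_vals = sorted({float(v) for v in model.lower_bounds}
                        | {float(v) for v in model.upper_bounds})
    bound_pid = {v: f"B_{i}" for i, v in enumerate(bound_vals)}
    params = etree.SubElement(mnode, _q(SBML_NS, "listOfParameters"))
    for v, pid in bound_pid.items():
        p = etree.SubElement(params, _q(SBML_NS, "parameter"))
        p.set("id", pid)
        p.set("value", repr(v))
        p.set("constant", "true")

    rxns = etree.SubElement(mnode, _q(SBML_NS, "listOfReactions"))
    S = model.S.tocsc()
    for j, rid in enumerate(model.reaction_ids):
        r = etree.SubElement(rxns, _q(SBML_NS, "reaction"))
        r.set("id", _encode_sid(rid, "R_"))
        r.set("name", rid)
        r.set("reversible", "true" if model.lower_bounds[j] < 0 else "false")
        r.set("fast", "false")
        r.set(_q(FBC_NS, "lowerFluxBound"), bound_pid[float(model.lower_bounds[j])])
        r.set(_q(FBC_NS, "upperFluxBound"), bound_pid[float(model.upper_bounds[j])])
        col = S.getcol(j).tocoo()
        reactants = [(i, v) for i, v in zip(col.row, col.data) if v < 0]
        products = [(i, v) for i, v in zip(col.row, col.data) if v > 0]
        if reactants:
            lst = etree.SubElement(r, _q(SBML_NS, "listOfReactants"))
            for i, v in reactants:
                sr = etree.SubElement(lst, _q(SBML_NS, "speciesReference"))
                sr.set("species", _encode_sid(model.metabolite_ids[i], "M_"))
                sr.set("stoichiometry", repr(-float(v)))
                sr.set("constant", "true")
        if products:
            lst = etree.SubElement(r, _q(SBML_NS, "listOfProducts"))
            for i, v in products:
                sr = etree.SubElement(lst, _q(SBML_NS, "speciesReference"))
                sr.set("species", _encode_sid(model.metabolite_ids[i], "M_"))
                sr.set("stoichiometry", repr(float(v)))
                sr.set("constant", "true")
        g = model.gpr_rules[j]
        if g is not None:
            assoc = etree.SubElement(r, _q(FBC_NS, "geneProductAssociation"))
            assoc.append(_gpr_to_xml(g))

    objs = etree.SubElement(mnode, _q(FBC_NS, "listOfObjectives"))
    objs.set(_q(FBC_NS, "activeObjective"), "obj")
    obj = etree.SubElement(objs, _q(FBC_NS, "objective"))
    obj.set(_q(FBC_NS, "id"), "obj")
    obj.set(_q(FBC_NS, "type"), "maximize")
    flux_objs = etree.SubElement(obj, _q(FBC_NS, "listOfFluxObjectives"))
    for j, rid in enumerate(model.reaction_ids):
        if model.objective_coeffs[j]:
            fo = etree.SubElement(flux_objs, _q(FBC_NS, "fluxObjective"))
            fo.set(_q(FBC_NS, "reaction"), _encode_sid(rid, "R_"))
            fo.set(_q(FBC_NS, "coefficient"), repr(float(model.objective_coeffs[j])))

    if model.gene_ids:
        gps = etree.SubElement(mnode, _q(FBC_NS, "listOfGeneProducts"))
        for gid in model.gene_ids:
            gp = etree.SubElement(gps, _q(FBC_NS, "geneProduct"))
            gp.set(_q(FBC_NS, "id"), _encode_sid(gid, "G_"))
            gp.set(_q(FBC_NS, "label"), gid)

    subsystems = {}
    for j, sub in enumerate(model.subsystems):
        if sub:
            subsystems.setdefault(sub, []).append(model.reaction_ids[j])
    if subsystems:
        groups = etree.SubElement(mnode, _q(GROUPS_NS, "listOfGroups"))
        for i, (sub, rids) in enumerate(subsystems.items()):
            grp = etree.SubElement(groups, _q(GROUPS_NS, "group"))
            grp.set(_q(GROUPS_NS, "id"), f"group_{i}")
            grp.set(_q(GROUPS_NS, "name"), sub)
            grp.set(_q(GROUPS_NS, "kind"), "partition")
            members = etree.SubElement(grp, _q(GROUPS_NS, "listOfMembers"))
            for rid in rids:
                mem = etree.SubElement(members, _q(GROUPS_NS, "member"))
                mem.set(_q(GROUPS_NS, "idRef"), _encode_sid(rid, "R_"))

    tree = etree.ElementTree(root)
    tree.write(str(path), xml_declaration=True, encoding="UTF-8",
               pretty_print=True)


def _gpr_to_xml(node: GPR) -> etree._Element:
    if node.op == "gene":
        el = etree.Element(_q(FBC_NS, "geneProductRef"))
        el.set(_q(FBC_NS, "geneProduct"), _encode_sid(node.gene, "G_"))
        return el
    el = etree.Element(_q(FBC_NS, node.op))
    for child in node.children:
        el.append(_gpr_to_xml(child))
    return el


def _xml_to_gpr(el: etree._Element, gene_names: dict[str, str]) -> GPR:
    tag = etree.QName(el).localname
    if tag == "geneProductRef":
        sid = el.get(_q(FBC_NS, "geneProduct"))
        if sid is None or sid not in gene_names:
            raise ModelFormatError(
                f"geneProductRef references undeclared gene product {sid!r}")
        return GPR.gene_(gene_names[sid])
    if tag in ("and", "or"):
        children = [_xml_to_gpr(c, gene_names) for c in el
                    if isinstance(c.tag, str)]
        if len(children) == 1:
            return children[0]
        return GPR(tag, children=children)
    raise ModelFormatError(f"unsupported element <{tag}> in gene association")


def _read_sbml(path: Path) -> MetabolicModel:
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise ModelFormatError(f"{path}: not well-formed XML ({exc})") from exc
    root = tree.getroot()
    if etree.QName(root).localname != "sbml":
        raise ModelFormatError(f"{path}: root element is <{root.tag}>, not <sbml>")
    mnode = root.find(_q(SBML_NS, "model"))
    if mnode is None:
        raise ModelFormatError(f"{path}: no <model> element")
    raw_id = mnode.get("id", "model")
    model_id = mnode.get("name") or (
        _decode_sid(raw_id, "MOD_") if raw_id.startswith("MOD_") else raw_id)

    params: dict[str, float] = {}
    for p in mnode.findall(f"{_q(SBML_NS, 'listOfParameters')}/{_q(SBML_NS, 'parameter')}"):
        if p.get("value") is not None:
            params[p.get("id")] = float(p.get("value"))

    met_ids: list[str] = []
    sid_to_met: dict[str, str] = {}
    for s in mnode.findall(f"{_q(SBML_NS, 'listOfSpecies')}/{_q(SBML_NS, 'species')}"):
        sid = s.get("id")
        mid = _decode_sid(sid, "M_") if sid.startswith("M_") else sid
        sid_to_met[sid] = mid
        met_ids.append(mid)

    gene_names: dict[str, str] = {}
    gene_order: list[str] = []
    for gp in mnode.findall(f"{_q(FBC_NS, 'listOfGeneProducts')}/{_q(FBC_NS, 'geneProduct')}"):
        sid = gp.get(_q(FBC_NS, "id"))
        label = gp.get(_q(FBC_NS, "label"))
        # prefer decoding the SId (both we and cobra escape it reversibly);
        # some writers put the prefixed id into the label as well
        name = _decode_sid(sid, "G_") if sid.startswith("G_") else (label or sid)
        gene_names[sid] = name
        gene_order.append(name)

    reactions = []
    gprs: dict[str, Optional[GPR]] = {}
    rid_by_sid: dict[str, str] = {}
    for r in mnode.findall(f"{_q(SBML_NS, 'listOfReactions')}/{_q(SBML_NS, 'reaction')}"):
        sid = r.get("id")
        rid = _decode_sid(sid, "R_") if sid.startswith("R_") else sid
        rid_by_sid[sid] = rid
        lb_ref = r.get(_q(FBC_NS, "lowerFluxBound"))
        ub_ref = r.get(_q(FBC_NS, "upperFluxBound"))
        if lb_ref is None or ub_ref is None:
            raise ModelFormatError(
                f"{path}: reaction {rid!r} lacks fbc flux bound attributes")
        if lb_ref not in params or ub_ref not in params:
            raise ModelFormatError(
                f"{path}: reaction {rid!r} references undefined bound parameter")
        stoich: dict[str, float] = {}
        for sr in r.findall(f"{_q(SBML_NS, 'listOfReactants')}/{_q(SBML_NS, 'speciesReference')}"):
            mid = sid_to_met.get(sr.get("species"))
            if mid is None:
                raise ModelFormatError(
                    f"{path}: reaction {rid!r} references unknown species "
                    f"{sr.get('species')!r}")
            stoich[mid] = stoich.get(mid, 0.0) - float(sr.get("stoichiometry", "1"))
        for sr in r.findall(f"{_q(SBML_NS, 'listOfProducts')}/{_q(SBML_NS, 'speciesReference')}"):
            mid = sid_to_met.get(sr.get("species"))
            if mid is None:
                raise ModelFormatError(
                    f"{path}: reaction {rid!r} references unknown species "
                    f"{sr.get('species')!r}")
            stoich[mid] = stoich.get(mid, 0.0) + float(sr.get("stoichiometry", "1"))
        reactions.append((rid, stoich, params[lb_ref], params[ub_ref]))
        assoc = r.find(_q(FBC_NS, "geneProductAssociation"))
        if assoc is not None:
            children = [c for c in assoc if isinstance(c.tag, str)]
            if len(children) != 1:
                raise ModelFormatError(
                    f"{path}: reaction {rid!r} has a malformed gene association")
            gprs[rid] = _xml_to_gpr(children[0], gene_names)
        else:
            gprs[rid] = None

    objective: dict[str, float] = {}
    objs = mnode.find(_q(FBC_NS, "listOfObjectives"))
    if objs is not None:
        active = objs.get(_q(FBC_NS, "activeObjective"))
        for o in objs.findall(_q(FBC_NS, "objective")):
            if active is not None and o.get(_q(FBC_NS, "id")) != active:
                continue
            for fo in o.findall(f"{_q(FBC_NS, 'listOfFluxObjectives')}/{_q(FBC_NS, 'fluxObjective')}"):
                rsid = fo.get(_q(FBC_NS, "reaction"))
                rid = rid_by_sid.get(rsid)
                if rid is None:
                    raise ModelFormatError(
                        f"{path}: objective references unknown reaction {rsid!r}")
                objective[rid] = float(fo.get(_q(FBC_NS, "coefficient"), "0"))

    subsystems: dict[str, str] = {}
    for grp in mnode.findall(f"{_q(GROUPS_NS, 'listOfGroups')}/{_q(GROUPS_NS, 'group')}"):
        name = grp.get(_q(GROUPS_NS, "name")) or grp.get(_q(GROUPS_NS, "id"))
        for mem in grp.findall(f"{_q(GROUPS_NS, 'listOfMembers')}/{_q(GROUPS_NS, 'member')}"):
            ref = mem.get(_q(GROUPS_NS, "idRef"))
            rid = rid_by_sid.get(ref)
            if rid is not None:
                subsystems[rid] = name

    gpr_strings = {rid: (g.to_string() if g is not None else "")
                   for rid, g in gprs.items()}
    model = build_model(reactions, gprs=gpr_strings, subsystems=subsystems,
                        objective=objective, model_id=model_id)
    model = _reorder_metabolites(model, met_ids, path)
    if gene_order:
        _check_gene_cover(model, gene_order, path)
        model.gene_ids = gene_order
    return model
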