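"""Read, validate, write and organize QSA(P)R model definitions (XML dialect).

User-defined models travel as plain-text XML.  The dialect (documented in
the README and mirrored by `write_model_xml`):

.. code-block:: xml

    <qsar_model type="mlr|lda" version="1">
      <metadata id=".." endpoint=".." units=".." group=".." subgroup="..">
        <citation>free text</citation>
      </metadata>
      <descriptors>
        <descriptor name="logKow" source="computed|supplied">text</descriptor>
      </descriptors>
      <training>
        <chemical id="c1" smiles="CCO">
          <value d="logKow">0.46</value>
          <endpoint>3.2</endpoint>          <!-- class label text for LDA -->
        </chemical>
      </training>
      <coefficients intercept="1.0">        <!-- optional, MLR only -->
        <coef d="logKow">2.0</coef>
      </coefficients>
    </qsar_model>

A model always carries its training data, because every applicability-domain
statistic needs the training matrix; the optional ``<coefficients>`` block is
verified against the refit (tolerance 1e-6) rather than trusted.  Reals are
serialized with 17 significant digits so a write→parse round trip is
lossless for doubles.

The registry configuration is a plain key-value text file::

    # lines starting with '#' are comments
    model_dir = models
    assign my_model = Ecotoxicity / Fish pLC50   # optional group override
"""

from __future__ import annotations

import logging
import warnings
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np

from .base import (
    DescriptorSpec,
    ModelMetadata,
    QsarError,
    TrainingRecord,
    ValidationError,
)
from .lda import LdaModel, fit_lda
from .mlr import MlrModel, fit_mlr

logger = logging.getLogger("qsarprofiler.model_io")

__all__ = [
    "ModelParseError",
    "ModelRegistry",
    "parse_model_xml",
    "write_model_xml",
    "load_registry",
    "read_model_file",
    "write_model_file",
]

COEFFICIENT_TOLERANCE = 1e-6


class ModelParseError(QsarError):
    """The document violates the model XML schema (names the element)."""


def _real(text: str, where: str) -> float:
    try:
        return float(text)
    except (TypeError, ValueError):
        raise ModelParseError(f"element <{where}> does not contain a real number: "
                              f"{text!r}") from None


def _require(elem, tag: str):
    child = elem.find(tag)
    if child is None:
        raise ModelParseError(f"missing required element <{tag}> under <{elem.tag}>")
    return child


def parse_model_xml(document: str) -> Union[MlrModel, LdaModel]:
    """Parse a model XML document into a fitted MlrModel or LdaModel.

    The model is refit from its training data; a ``<coefficients>`` block, if
    present, must agree with the refit to 1e-6 per coefficient or a
    ValidationError is raised (a published model whose stated coefficients
    contradict its stated training set is broken and should not predict).
    """
    try:
        root = ET.fromstring(document)
    except ET.ParseError as exc:
        raise ModelParseError(f"not well-formed XML: {exc}") from None
    if root.tag != "qsar_model":
        raise ModelParseError(f"root element must be <qsar_model>, got <{root.tag}>")
    mtype = root.get("type")
    if mtype not in ("mlr", "lda"):
        raise ModelParseError(
            f"<qsar_model> attribute type must be 'mlr' or 'lda', got {mtype!r}"
        )

    meta_el = _require(root, "metadata")
    model_id = meta_el.get("id")
    if not model_id:
        raise ModelParseError("<metadata> must carry a non-empty id attribute")
    citation_el = meta_el.find("citation")
    metadata = ModelMetadata(
        model_id=model_id,
        endpoint_name=meta_el.get("endpoint", ""),
        units=meta_el.get("units", ""),
        group=meta_el.get("group", ""),
        subgroup=meta_el.get("subgroup", ""),
        citation=(citation_el.text or "") if citation_el is not None else "",
    )

    desc_el = _require(root, "descriptors")
    specs = []
    for d in desc_el.findall("descriptor"):
        name = d.get("name")
        if not name:
            raise ModelParseError("<descriptor> must carry a non-empty name attribute")
        specs.append(DescriptorSpec(name=name, source=d.get("source", "computed"),
                                    description=(d.text or "").strip()))
    if not specs:
        raise ModelParseError("<descriptors> must list at least one <descriptor>")
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ModelParseError(f"duplicate <descriptor> names: {sorted(set(n for n in names if names.count(n) > 1))}")

    train_el = _require(root, "training")
    training = []
    for chem in train_el.findall("chemical"):
        cid = chem.get("id")
        if not cid:
            raise ModelParseError("<chemical> must carry a non-empty id attribute")
        values_by_name = {}
        for v in chem.findall("value"):
            dname = v.get("d")
            if dname not in names:
                raise ModelParseError(
                    f"chemical {cid!r}: <value d={dname!r}> names no declared descriptor"
                )
            if dname in values_by_name:
                raise ModelParseError(f"chemical {cid!r}: duplicate value for {dname!r}")
            values_by_name[dname] = _real(v.text, f"value d={dname!r}")
        if set(values_by_name) != set(names):
            missing = sorted(set(names) - set(values_by_name))
            extra = len(values_by_name) - len(set(values_by_name) & set(names))
            raise ModelParseError(
                f"chemical {cid!r} has {len(values_by_name)} descriptor values, "
                f"model declares {len(names)}"
                + (f"; missing {missing}" if missing else "")
            )
        ep = _require(chem, "endpoint")
        if ep.text is None or not ep.text.strip():
            raise ModelParseError(f"chemical {cid!r}: empty <endpoint>")
        y: Union[float, str]
        if mtype == "mlr":
            y = _real(ep.text.strip(), "endpoint")
        else:
            y = ep.text.strip()
        training.append(
            TrainingRecord(id=cid, smiles=chem.get("smiles"),
                           descriptor_values=tuple(values_by_name[n] for n in names),
                           y=y)
        )
    if not training:
        raise ModelParseError("<training> must list at least one <chemical>")

    coef_el = root.find("coefficients")
    if mtype == "lda":
        if coef_el is not None:
            raise ModelParseError("<coefficients> is only valid for type='mlr'")
        try:
            return fit_lda(specs, training, metadata=metadata)
        except ValidationError as exc:
            raise ValidationError(f"model {model_id!r}: {exc}") from None

    try:
        model = fit_mlr(specs, training, metadata=metadata)
    except ValidationError as exc:
        raise ValidationError(f"model {model_id!r}: {exc}") from None

    if coef_el is not None:
        stated = [_real(coef_el.get("intercept"), "coefficients intercept=..")]
        by_name = {}
        for c in coef_el.findall("coef"):
            dname = c.get("d")
            if dname not in names:
                raise ModelParseError(f"<coef d={dname!r}> names no declared descriptor")
            by_name[dname] = _real(c.text, f"coef d={dname!r}")
        if set(by_name) != set(names):
            raise ModelParseError("a <coef> is required for every descriptor")
        stated.extend(by_name[n] for n in names)
        delta = np.max(np.abs(np.asarray(stated) - model.beta))
        if delta > COEFFICIENT_TOLERANCE:
            raise ValidationError(
                f"model {model_id!r}: stated coefficients disagree with the "
                f"training-data fit by up to {delta:.3g} (tolerance "
                f"{COEFFICIENT_TOLERANCE:g})"
            )
    return model


def _fmt(x: float) -> str:
    return format(float(x), ".17g")


def write_model_xml(model: Union[MlrModel, LdaModel],
                    include_coefficients: bool = True) -> str:
    """Serialize a fitted model; parse(write(m)) equals m field by field."""
    mtype = model.model_type
    root = ET.Element("qsar_model", {"type": mtype, "version": "1"})
    md = model.metadata
    meta = ET.SubElement(root, "metadata", {
        "id": md.model_id, "endpoint": md.endpoint_name, "units": md.units,
        "group": md.group, "subgroup": md.subgroup,
    })
    if md.citation:
        ET.SubElement(meta, "citation").text = md.citation
    descs = ET.SubElement(root, "descriptors")
    for spec in model.specs:
        d = ET.SubElement(descs, "descriptor", {"name": spec.name,
                                                "source": spec.source})
        if spec.description:
            d.text = spec.description
    train = ET.SubElement(root, "training")
    for rec in model.training:
        attrs = {"id": rec.id}
        if rec.smiles:
            attrs["smiles"] = rec.smiles
        chem = ET.SubElement(train, "chemical", attrs)
        for spec, v in zip(model.specs, rec.descriptor_values):
            ET.SubElement(chem, "value", {"d": spec.name}).text = _fmt(v)
        ET.SubElement(chem, "endpoint").text = (
            _fmt(rec.y) if mtype == "mlr" else str(rec.y)
        )
    if mtype == "mlr" and include_coefficients:
        coefs = ET.SubElement(root, "coefficients",
                              {"intercept": _fmt(model.beta[0])})
        for spec, b in zip(model.specs, model.beta[1:]):
            ET.SubElement(coefs, "coef", {"d": spec.name}).text = _fmt(b)
    ET.indent(root)
    return ET.tostring(root, encoding="unicode", xml_declaration=True) + "\n"


def read_model_file(path) -> Union[MlrModel, LdaModel]:
    return parse_model_xml(Path(path).read_text(encoding="utf-8"))


def write_model_file(model, path) -> None:
    Path(path).write_text(write_model_xml(model), encoding="utf-8")


# ---------------------------------------------------------------------------
# registry
# ---------------------------------------------------------------------------

@dataclass
class ModelRegistry:
    """Validated models organized by (group, subgroup), in load order."""

    models: dict = field(default_factory=dict)  # model_id -> model
    diagnostics: list = field(default_factory=list)  # (path, message)

    def register(self, model, group: Optional[str] = None,
                 subgroup: Optional[str] = None) -> None:
        mid = model.metadata.model_id
        if mid in self.models:
            raise ValidationError(f"duplicate model id {mid!r} in registry")
        if group is not None or subgroup is not None:
            md = model.metadata
            model.metadata = ModelMetadata(
                model_id=md.model_id, endpoint_name=md.endpoint_name,
                units=md.units, group=group if group is not None else md.group,
                subgroup=subgroup if subgroup is not None else md.subgroup,
                citation=md.citation,
            )
        self.models[mid] = model

    def __len__(self) -> int:
        return len(self.models)

    def __iter__(self):
        return iter(self.models.values())

    def get(self, model_id: str):
        return self.models[model_id]

    def groups(self) -> dict:
        """Mapping (group, subgroup) -> [models], in registration order."""
        out: dict = {}
        for m in self.models.values():
            out.setdefault((m.metadata.group, m.metadata.subgroup), []).append(m)
        return out

    def in_subgroup(self, subgroup: str, group: Optional[str] = None) -> list:
        return [
            m for m in self.models.values()
            if m.metadata.subgroup == subgroup
            and (group is None or m.metadata.group == group)
        ]


def _parse_config(path: Path):
    model_dirs, assigns = [], {}
    for lineno, raw in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValidationError(f"{path}:{lineno}: expected 'key = value'")
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if key == "model_dir":
            model_dirs.append(value)
        elif key.startswith("assign "):
            mid = key[len("assign "):].strip()
            if "/" in value:
                grp, _, sub = value.partition("/")
                assigns[mid] = (grp.strip(), sub.strip())
            else:
                assigns[mid] = (value, "")
        else:
            raise ValidationError(f"{path}:{lineno}: unknown config key {key!r}")
    return model_dirs, assigns


def load_registry(config: Union[str, Path]) -> ModelRegistry:
    """Load every parseable model under the config's model directories.

    Unparseable or invalid files are reported in ``registry.diagnostics`` and
    logged, never fatal; an empty registry triggers a warning.  ``assign``
    lines override a model's group/subgroup.
    """
    config = Path(config)
    model_dirs, assigns = _parse_config(config)
    registry = ModelRegistry()
    for d in model_dirs:
        directory = (config.parent / d) if not Path(d).is_absolute() else Path(d)
        if not directory.is_dir():
            registry.diagnostics.append((str(directory), "not a directory"))
            logger.warning("registry: %s is not a directory", directory)
            continue
        for path in sorted(directory.glob("*.xml")):
            try:
                model = read_model_file(path)
            except QsarError as exc:
                registry.diagnostics.append((str(path), str(exc)))
                logger.warning("registry: skipping %s: %s", path, exc)
                continue
            grp_sub = assigns.get(model.metadata.model_id)
            if grp_sub:
                registry.register(model, group=grp_sub[0], subgroup=grp_sub[1])
            else:
                registry.register(model)
            logger.info("registry: loaded %s from %s", model.metadata.model_id, path)
    if len(registry) == 0:
        warnings.warn(f"registry loaded from {config} is empty", stacklevel=2)
    return registry
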