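"""Minimal, generic XSD 1.0 interpreter used to check instance documents
against an emitted schema without external dependencies.

Supported subset (all that the emitted schemas use): global/nested
``xs:element``, ``xs:complexType`` with ``xs:sequence`` and ``xs:choice``
particles (``minOccurs``/``maxOccurs``), attributes with ``use``,
``xs:simpleContent``/``xs:extension``, and global ``xs:simpleType``
restrictions of ``xs:string`` with ``xs:enumeration`` facets.  Base types:
``xs:string``, ``xs:decimal``, ``xs:integer``.

This validator is deliberately independent of the record model: it reads
the schema document itself and interprets it against the instance tree.
"""

from __future__ import annotations

import re
import xml.etree.ElementTree as ET

XS = "{http://www.w3.org/2001/XMLSchema}"

__all__ = ["validate_document", "XsdSchema"]


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _strip(name: str) -> str:
    """Drop a namespace prefix from a QName in schema content."""
    return name.split(":", 1)[-1] if ":" in name else name


_DECIMAL_RE = re.compile(r"^[+-]?(\d+(\.\d*)?|\.\d+)$")
_INTEGER_RE = re.compile(r"^[+-]?\d+$")


class XsdSchema:
    def __init__(self, xsd_source: str):
        root = ET.fromstring(xsd_source)
        if _local(root.tag) != "schema":
            raise ValueError("not an XSD document")
        self.target_namespace = root.get("targetNamespace")
        self.simple_types: dict[str, set | str] = {}
        self.complex_types: dict[str, ET.Element] = {}
        self.root_elements: dict[str, ET.Element] = {}
        for child in root:
            tag = _local(child.tag)
            if tag == "simpleType":
                self.simple_types[child.get("name")] = self._parse_simple(child)
            elif tag == "complexType":
                self.complex_types[child.get("name")] = child
            elif tag == "element":
                self.root_elements[child.get("name")] = child

    @staticmethod
    def _parse_simple(node: ET.Element):
        restriction = node.find(f"{XS}restriction")
        if restriction is None:
            return "string"
        enums = restriction.findall(f"{XS}enumeration")
        if enums:
            return {e.get("value") for e in enums}
        return _strip(restriction.get("base", "xs:string"))

    # ------------------------------------------------------------ checking
    def _check_simple(self, type_name: str, value: str, where: str,
                      errors: list[str]) -> None:
        t = self.simple_types.get(type_name, type_name)
        if isinstance(t, set):
            if value not in t:
                errors.append(
                    f"{where}: value {value!r} not in enumeration")
            return
        base = _strip(t)
        if base == "decimal" and not _DECIMAL_RE.match(value.strip()):
            errors.append(f"{where}: {value!r} is not a decimal")
        elif base == "integer" and not _INTEGER_RE.match(value.strip()):
            errors.append(f"{where}: {value!r} is not an integer")
        # string: anything goes

    def _element_type(self, decl: ET.Element):
        t = decl.get("type")
        if t is not None:
            return _strip(t)
        inline = decl.find(f"{XS}complexType")
        if inline is not None:
            return inline
        inline = decl.find(f"{XS}simpleType")
        return inline

    def _check_attributes(self, ctype: ET.Element, elem: ET.Element,
                          where: str, errors: list[str],
                          holder: ET.Element | None = None) -> None:
        holder = holder if holder is not None else ctype
        declared = {}
        for attr in holder.findall(f"{XS}attribute"):
            declared[attr.get("name")] = attr
        present = {k: v for k, v in elem.attrib.items()
                   if not k.startswith("xmlns") and _local(k) == k}
        for name, attr in declared.items():
            if attr.get("use") == "required" and name not in present:
                errors.append(f"{where}: missing required attribute {name!r}")
            if name in present and attr.get("type"):
                self._check_simple(_strip(attr.get("type")), present[name],
                                   f"{where}/@{name}", errors)
        for name in present:
            if name not in declared:
                errors.append(f"{where}: undeclared attribute {name!r}")

    def _check_element(self, decl: ET.Element, elem: ET.Element,
                       where: str, errors: list[str]) -> None:
        t = self._element_type(decl)
        if t is None:  # untyped: anything
            return
        if isinstance(t, str):
            if t in ("string", "decimal", "integer") or t in self.simple_types:
                if list(elem):
                    errors.append(f"{where}: simple-typed element has children")
                self._check_simple(t, elem.text or "", where, errors)
                return
            ctype = self.complex_types.get(t)
            if ctype is None:
                errors.append(f"{where}: unknown type {t!r}")
                return
        else:
            ctype = t
            if _local(ctype.tag) == "simpleType":
                self._check_simple("string", elem.text or "", where, errors)
                return
        simple = ctype.find(f"{XS}simpleContent")
        if simple is not None:
            ext = simple.find(f"{XS}extension")
            base = _strip(ext.get("base"))
            if list(elem):
                errors.append(f"{where}: simple-content element has children")
            self._check_simple(base, elem.text or "", where, errors)
            self._check_attributes(ctype, elem, where, errors, holder=ext)
            return
        self._check_attributes(ctype, elem, where, errors)
        if elem.text and elem.text.strip():
            errors.append(f"{where}: unexpected text content")
        particle = ctype.find(f"{XS}sequence")
        children = list(elem)
        if particle is None:
            if children:
                errors.append(f"{where}: unexpected child elements")
            return
        self._match_sequence(particle, children, where, errors)

    def _match_sequence(self, seq: ET.Element, children: list[ET.Element],
                        where: str, errors: list[str]) -> None:
        pos = 0
        for particle in seq:
            ptag = _local(particle.tag)
            lo = int(particle.get("minOccurs", "1"))
            hi_raw = particle.get("maxOccurs", "1")
            hi = None if hi_raw == "unbounded" else int(hi_raw)
            if ptag == "element":
                name = particle.get("name")
                n = 0
                while (pos < len(children) and (hi is None or n < hi)
                       and _local(children[pos].tag) == name):
                    self._check_element(particle, children[pos],
                                        f"{where}/{name}[{n}]", errors)
                    pos += 1
                    n += 1
                if n < lo:
                    errors.append(
                        f"{where}: expected at least {lo} <{name}> element(s), "
                        f"found {n}")
            elif ptag == "choice":
                members = {m.get("name"): m for m in particle
                           if _local(m.tag) == "element"}
                n = 0
                while (pos < len(children) and (hi is None or n < hi)
                       and _local(children[pos].tag) in members):
                    name = _local(children[pos].tag)
                    self._check_element(members[name], children[pos],
                                        f"{where}/{name}[{n}]", errors)
                    pos += 1
                    n += 1
                if n < lo:
                    errors.append(
                        f"{where}: expected at least {lo} of "
                        f"{sorted(members)}, found {n}")
        if pos != len(children):
            extra = _local(children[pos].tag)
            errors.append(f"{where}: unexpected element <{extra}>")

    def validate(self, instance_source: str) -> list[str]:
        try:
            root = ET.fromstring(instance_source)
        except ET.ParseError as e:
            return [f"malformed XML: {e}"]
        errors: list[str] = []
        name = _local(root.tag)
        ns = root.tag[1:].rsplit("}", 1)[0] if root.tag.startswith("{") else None
        if self.target_namespace and ns != self.target_namespace:
            errors.append(
                f"root namespace {ns!r} does not match target namespace "
                f"{self.target_namespace!r}")
        decl = self.root_elements.get(name)
        if decl is None:
            errors.append(f"no global element declaration for <{name}>")
            return errors
        self._check_element(decl, root, f"/{name}", errors)
        return errors


def validate_document(xsd_source: str, instance_source: str) -> list[str]:
    """Validate an instance document against a schema document; returns a
    list of human-readable violations (empty = valid)."""
    return XsdSchema(xsd_source).validate(instance_source)
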