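"""Machine-readable workflow provenance.

Every pipeline step is captured as a record with a fresh UUID (version 4),
the operation name, the exact parameters, and the UUIDs of its input and
output objects.  Objects (files, tables, reports) live in a registry that
stores their role, location and a content digest (SHA-256 over file bytes)
so results can be integrity-checked later.

A workflow document satisfies the *chain property*: every input of every
step is either a registered external input or the output of an earlier
step.  Export serializes the records in a valid topological order of the
data-dependency graph as JSON; import reconstructs an equal document.
Documents violating the chain property (dangling inputs, dependency
cycles) are refused, never silently repaired.
"""

from __future__ import annotations

import hashlib
import json
import uuid as uuid_module
from dataclasses import dataclass, field
from datetime import datetime, timezone
from graphlib import CycleError, TopologicalSorter
from pathlib import Path
from typing import Dict, List, Optional, Sequence

SCHEMA_VERSION = "1.0"
DIGEST_ALGORITHM = "sha256"


class ProvenanceError(ValueError):
    """Raised for chain violations, unknown uuids, or malformed documents."""


@dataclass
class RegisteredObject:
    """An entry in the object registry: a file, table or report."""

    uuid: str
    role: str  # "file" | "table" | "report"
    path: Optional[str] = None
    descriptor: Optional[str] = None
    digest: Optional[str] = None
    doi: Optional[str] = None

    def to_json(self) -> dict:
        return {
            "uuid": self.uuid,
            "role": self.role,
            "path": self.path,
            "descriptor": self.descriptor,
            "digest": self.digest,
            "doi": self.doi,
        }


@dataclass
class ProvenanceRecord:
    """One executed workflow step."""

    uuid: str
    operation: str
    tool_version: str
    parameters: Dict[str, object]
    input_ids: List[str]
    output_ids: List[str]
    started_at: str
    ended_at: str

    def to_json(self) -> dict:
        return {
            "uuid": self.uuid,
            "operation": self.operation,
            "tool_version": self.tool_version,
            "parameters": self.parameters,
            "input_ids": list(self.input_ids),
            "output_ids": list(self.output_ids),
            "started_at": self.started_at,
            "ended_at": self.ended_at,
        }


def _now() -> str:
    return datetime.now(timezone.utc).isoformat()


def file_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class WorkflowDocument:
    """A provenance trail: step records plus the object registry."""

    records: List[ProvenanceRecord] = field(default_factory=list)
    object_registry: Dict[str, RegisteredObject] = field(default_factory=dict)
    #: uuids registered directly (not produced by any step)
    external_ids: List[str] = field(default_factory=list)

    # -- object registration -------------------------------------------------

    def register_object(
        self,
        role: str,
        path=None,
        descriptor: Optional[str] = None,
        external: bool = True,
        compute_digest: bool = True,
    ) -> str:
        """Register an object and return its fresh uuid.  ``external=True``
        marks it as a workflow input that no step produced."""
        if role not in {"file", "table", "report"}:
            raise ProvenanceError(f"unknown object role {role!r}")
        oid = str(uuid_module.uuid4())
        digest = None
        if path is not None and compute_digest and Path(path).exists():
            digest = file_digest(path)
        self.object_registry[oid] = RegisteredObject(
            uuid=oid,
            role=role,
            path=str(path) if path is not None else None,
            descriptor=descriptor,
            digest=digest,
        )
        if external:
            self.external_ids.append(oid)
        return oid

    # -- step recording ------------------------------------------------------

    def record_step(
        self,
        operation: str,
        parameters: Optional[Dict[str, object]] = None,
        inputs: Sequence[str] = (),
        outputs: Sequence[str] = (),
        tool_version: str = "",
        started_at: Optional[str] = None,
        ended_at: Optional[str] = None,
    ) -> ProvenanceRecord:
        """Append one step.  All inputs must already be registered; outputs
        must be registered and not previously produced or passed in as the
        step's own inputs."""
        produced = {oid for rec in self.records for oid in rec.output_ids}
        available = set(self.external_ids) | produced
        for oid in inputs:
            if oid not in self.object_registry:
                raise ProvenanceError(f"input uuid {oid} is not registered")
            if oid not in available:
                raise ProvenanceError(
                    f"input uuid {oid} is neither an external input nor a "
                    "prior step output"
                )
        out_set = set(outputs)
        if out_set & set(inputs):
            raise ProvenanceError("a step's outputs must be disjoint from its inputs")
        for oid in outputs:
            if oid not in self.object_registry:
                raise ProvenanceError(f"output uuid {oid} is not registered")
            if oid in produced:
                raise ProvenanceError(f"output uuid {oid} was already produced")
            if oid in self.external_ids:
                raise ProvenanceError(
                    f"output uuid {oid} is registered as an external input"
                )
        started = started_at or _now()
        record = ProvenanceRecord(
            uuid=str(uuid_module.uuid4()),
            operation=operation,
            tool_version=tool_version,
            parameters=dict(parameters or {}),
            input_ids=list(inputs),
            output_ids=list(outputs),
            started_at=started,
            ended_at=ended_at or _now(),
        )
        if record.ended_at < record.started_at:
            raise ProvenanceError("ended_at precedes started_at")
        self.records.append(record)
        return record

    # -- validation ----------------------------------------------------------

    def validate(self) -> None:
        """Check the chain property; raise :class:`ProvenanceError` on any
        dangling input, duplicate output, or dependency cycle."""
        seen_step_ids = set()
        produced: Dict[str, str] = {}  # object uuid -> producing step uuid
        for rec in self.records:
            if rec.uuid in seen_step_ids:
                raise ProvenanceError(f"duplicate step uuid {rec.uuid}")
            seen_step_ids.add(rec.uuid)
            for oid in rec.output_ids:
                if oid in produced:
                    raise ProvenanceError(
                        f"object {oid} produced by two steps"
                    )
                if oid in self.external_ids:
                    raise ProvenanceError(
                        f"object {oid} is both external and a step output"
                    )
                produced[oid] = rec.uuid
        external = set(self.external_ids)
        graph: Dict[str, set] = {rec.uuid: set() for rec in self.records}
        for rec in self.records:
            for oid in rec.input_ids:
                if oid not in self.object_registry:
                    raise ProvenanceError(f"input uuid {oid} is not registered")
                if oid in produced:
                    graph[rec.uuid].add(produced[oid])
                elif oid not in external:
                    raise ProvenanceError(
                        f"dangling input {oid}: not external, produced by no step"
                    )
        try:
            list(TopologicalSorter(graph).static_order())
        except CycleError as exc:
            raise ProvenanceError(f"dependency cycle: {exc}") from exc

    def topological_records(self) -> List[ProvenanceRecord]:
        """Records in a valid topological order of the dependency graph
        (deterministic: ties broken by append order)."""
        produced = {
            oid: rec.uuid for rec in self.records for oid in rec.output_ids
        }
        order_index = {rec.uuid: i for i, rec in enumerate(self.records)}
        graph = {
            rec.uuid: {
                produced[oid] for oid in rec.input_ids if oid in produced
            }
            for rec in self.records
        }
        sorter = TopologicalSorter(graph)
        sorter.prepare()
        ordered: List[str] = []
        while sorter.is_active():
            ready = sorted(sorter.get_ready(), key=order_index.__getitem__)
            ordered.extend(ready)
            sorter.done(*ready)
        by_id = {rec.uuid: rec for rec in self.records}
        return [by_id[sid] for sid in ordered]


def export_workflow(document: WorkflowDocument) -> str:
    """Serialize a validated document as JSON text (records in topological
    order)."""
    document.validate()
    payload = {
        "schema_version": SCHEMA_VERSION,
        "digest_algorithm": DIGEST_ALGORITHM,
        "external_ids": list(document.external_ids),
        "objects": [
            obj.to_json() for obj in document.object_registry.values()
        ],
        "records": [rec.to_json() for rec in document.topological_records()],
    }
    return json.dumps(payload, indent=2, sort_keys=False)


def import_workflow(text: str) -> WorkflowDocument:
    """Parse exported JSON back into a document, re-validating the chain."""
    try:
        payload = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ProvenanceError(f"invalid JSON: {exc}") from exc
    for key in ("objects", "records", "external_ids"):
        if key not in payload:
            raise ProvenanceError(f"document missing {key!r}")
    doc = WorkflowDocument()
    doc.external_ids = list(payload["external_ids"])
    for obj in payload["objects"]:
        doc.object_registry[obj["uuid"]] = RegisteredObject(
            uuid=obj["uuid"],
            role=obj["role"],
            path=obj.get("path"),
            descriptor=obj.get("descriptor"),
            digest=obj.get("digest"),
            doi=obj.get("doi"),
        )
    for rec in payload["records"]:
        doc.records.append(
            ProvenanceRecord(
                uuid=rec["uuid"],
                operation=rec["operation"],
                tool_version=rec.get("tool_version", ""),
                parameters=rec.get("parameters", {}),
                input_ids=list(rec["input_ids"]),
                output_ids=list(rec["output_ids"]),
                started_at=rec["started_at"],
                ended_at=rec["ended_at"],
            )
        )
    doc.validate()
    return doc


def load_or_new(path) -> WorkflowDocument:
    """Load a workflow JSON file if it exists, else start a fresh document."""
    p = Path(path)
    if p.exists():
        return import_workflow(p.read_text())
    return WorkflowDocument()


def save(document: WorkflowDocument, path) -> None:
    Path(path).write_text(export_workflow(document))
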