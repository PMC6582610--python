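"""Reading and writing instances, solutions, and run manifests.

Two instance dialects are supported and auto-detected:

* JSON: ``{"name": str, "a": [int...], "b": [int...], "c": [int...]}``
* 3-line whitespace-separated integers, line order a, b, c.

Invalid instances (unequal totals) load fine — the validity report travels
with the instance so they can be diagnosed rather than rejected at parse
time.  Negative lengths are a parse-level domain error.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

from . import __version__
from .core import DDPInstance, DigestMapError, SolutionRecord, ValidityReport, validate

__all__ = [
    "read_instance",
    "write_instance",
    "solution_to_dict",
    "solution_from_dict",
    "make_manifest",
    "file_digest",
]


def read_instance(path) -> tuple[DDPInstance, ValidityReport]:
    """Load an instance (JSON or 3-line text) plus its validity report."""
    path = Path(path)
    text = path.read_text()
    stripped = text.lstrip()
    if stripped.startswith("{"):
        try:
            obj = json.loads(text)
        except json.JSONDecodeError as e:
            raise DigestMapError(f"{path}: malformed JSON at line {e.lineno}: {e.msg}") from e
        missing = [f for f in ("a", "b", "c") if f not in obj]
        if missing:
            raise DigestMapError(f"{path}: missing field(s) {missing}")
        try:
            inst = DDPInstance(
                a=obj["a"], b=obj["b"], c=obj["c"], name=str(obj.get("name", path.stem))
            )
        except (TypeError, ValueError) as e:
            raise DigestMapError(f"{path}: {e}") from e
    else:
        lines = [ln for ln in text.splitlines() if ln.strip()]
        if len(lines) != 3:
            raise DigestMapError(f"{path}: text dialect needs exactly 3 non-empty lines, got {len(lines)}")
        vecs = []
        for lineno, ln in enumerate(lines, start=1):
            try:
                vecs.append(tuple(int(tok) for tok in ln.split()))
            except ValueError as e:
                raise DigestMapError(f"{path}: line {lineno}: non-integer token") from e
        try:
            inst = DDPInstance(a=vecs[0], b=vecs[1], c=vecs[2], name=path.stem)
        except ValueError as e:
            raise DigestMapError(f"{path}: {e}") from e
    return inst, validate(inst)


def write_instance(inst: DDPInstance, path, dialect: str = "json") -> None:
    path = Path(path)
    if dialect == "json":
        payload = {"name": inst.name, "a": list(inst.a), "b": list(inst.b), "c": list(inst.c)}
        path.write_text(json.dumps(payload, indent=1) + "\n")
    elif dialect == "text":
        path.write_text(
            "\n".join(" ".join(str(x) for x in v) for v in (inst.a, inst.b, inst.c)) + "\n"
        )
    else:
        raise DigestMapError(f"unknown dialect {dialect!r}")


def solution_to_dict(rec: SolutionRecord) -> dict:
    return {
        "mu": list(rec.mu),
        "nu": list(rec.nu),
        "pi": list(rec.pi) if rec.pi is not None else None,
        "dds": list(rec.dds),
        "mismatch": rec.mismatch,
        "fitness": rec.fitness,
        "generation_found": rec.generation_found,
    }


def solution_from_dict(obj: dict) -> SolutionRecord:
    return SolutionRecord(
        mu=tuple(obj["mu"]),
        nu=tuple(obj["nu"]),
        pi=tuple(obj["pi"]) if obj.get("pi") is not None else None,
        dds=tuple(obj["dds"]),
        mismatch=int(obj["mismatch"]),
        fitness=float(obj["fitness"]),
        generation_found=int(obj.get("generation_found", 0)),
    )


def file_digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (tuple, list)):
        return [_jsonable(x) for x in obj]
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    return obj


def make_manifest(command: str, config=None, seed=None, input_path=None) -> dict:
    """Provenance block embedded in every CLI artifact.

    Reruns with equal manifests (timestamp aside) produce equal outputs.
    """
    manifest = {
        "command": command,
        "package": "digestmap",
        "version": __version__,
        "seed": seed,
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    if config is not None:
        manifest["config"] = _jsonable(config)
    if input_path is not None:
        manifest["input"] = str(input_path)
        manifest["input_sha256"] = file_digest(input_path)
    return manifest
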