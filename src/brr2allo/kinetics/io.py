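"""Plain-text serialization of kinetic traces and binding schemes.

Trace format: a header block of ``# key=value`` metadata lines followed by
two whitespace-delimited columns (time_s, signal).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .model import BindingScheme, BindingSite, ExperimentSpec, KineticTrace

__all__ = [
    "write_trace",
    "read_trace",
    "scheme_to_json",
    "scheme_from_json",
    "spec_to_json",
    "spec_from_json",
]


def write_trace(trace: KineticTrace, path: str | Path) -> None:
    path = Path(path)
    lines = [f"# {k}={v}" for k, v in sorted(trace.meta.items())]
    lines.append("# columns=time_s signal")
    for t, s in zip(trace.time, trace.signal):
        lines.append(f"{t:.10g} {s:.10g}")
    path.write_text("\n".join(lines) + "\n")


def _parse_meta_value(raw: str):
    for cast in (int, float):
        try:
            return cast(raw)
        except ValueError:
            pass
    if raw == "None":
        return None
    return raw


def read_trace(path: str | Path) -> KineticTrace:
    meta: dict = {}
    times: list[float] = []
    signals: list[float] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, raw = body.partition("=")
                meta[key.strip()] = _parse_meta_value(raw.strip())
            continue
        fields = line.split()
        if len(fields) != 2:
            raise ValueError(f"malformed trace line: {line!r}")
        times.append(float(fields[0]))
        signals.append(float(fields[1]))
    meta.pop("columns", None)
    return KineticTrace(np.array(times), np.array(signals), meta)


def scheme_to_json(scheme: BindingScheme) -> str:
    return json.dumps(
        {
            "protein_conc": scheme.protein_conc,
            "baseline": scheme.baseline,
            "sites": [
                {
                    "label": s.label,
                    "k_on": s.k_on,
                    "k_off": s.k_off,
                    "amplitude": s.amplitude,
                }
                for s in scheme.sites
            ],
        },
        indent=1,
    )


def scheme_from_json(text: str) -> BindingScheme:
    obj = json.loads(text)
    sites = tuple(BindingSite(**site) for site in obj["sites"])
    return BindingScheme(sites, obj["protein_conc"], obj.get("baseline", 1.0))


def spec_to_json(spec: ExperimentSpec) -> str:
    return json.dumps(
        {
            "mode": spec.mode,
            "nucleotide_conc": spec.nucleotide_conc,
            "time_span": list(spec.time_span),
            "n_points": spec.n_points,
            "sampling": spec.sampling,
            "chase_conc": spec.chase_conc,
        },
        indent=1,
    )


def spec_from_json(text: str) -> ExperimentSpec:
    obj = json.loads(text)
    obj["time_span"] = tuple(obj["time_span"])
    return ExperimentSpec(**obj)
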