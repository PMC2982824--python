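"""Flat key=value scenario files for power calculations.

Recognised keys::

    n = 2000
    alpha = 0.025
    sided = one
    sigma = 1.0
    p_covariates = 0
    candidate.maf = 0.2
    candidate.effect = 0.1
    conditional[0].maf = 0.3
    conditional[0].effect = 0.1
    conditional[1].maf = 0.4
    conditional[1].effect = 0.1

Lines starting with '#' and blank lines are ignored.
"""

from __future__ import annotations

import re
from pathlib import Path

from .power import PowerScenario, SNPSpec

_COND_RE = re.compile(r"conditional\[(\d+)\]\.(maf|effect)$")


def read_scenario(path) -> PowerScenario:
    """Parse a flat key=value scenario file into a :class:`PowerScenario`."""
    scalars: dict[str, str] = {}
    cond: dict[int, dict[str, float]] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        m = _COND_RE.match(key)
        if m:
            cond.setdefault(int(m.group(1)), {})[m.group(2)] = float(value)
        else:
            scalars[key] = value
    for i, fields in cond.items():
        if set(fields) != {"maf", "effect"}:
            raise ValueError(f"conditional[{i}] needs both maf and effect")
    try:
        candidate = SNPSpec(
            "candidate",
            float(scalars["candidate.maf"]),
            float(scalars.get("candidate.effect", 0.0)),
        )
    except KeyError as exc:
        raise ValueError(f"scenario file missing required key {exc}") from None
    conditional = tuple(
        SNPSpec(f"conditional{i}", cond[i]["maf"], cond[i]["effect"])
        for i in sorted(cond)
    )
    return PowerScenario(
        n_subjects=int(scalars["n"]),
        candidate=candidate,
        conditional=conditional,
        n_covariates=int(scalars.get("p_covariates", 0)),
        residual_sd=float(scalars.get("sigma", 1.0)),
        alpha=float(scalars.get("alpha", 0.025)),
        sided=scalars.get("sided", "one"),
    )


def write_scenario(scenario: PowerScenario, path) -> None:
    lines = [
        f"n = {scenario.n_subjects}",
        f"alpha = {scenario.alpha}",
        f"sided = {scenario.sided}",
        f"sigma = {scenario.residual_sd}",
        f"p_covariates = {scenario.n_covariates}",
        f"candidate.maf = {scenario.candidate.maf}",
        f"candidate.effect = {scenario.candidate.effect}",
    ]
    for i, snp in enumerate(scenario.conditional):
        lines.append(f"conditional[{i}].maf = {snp.maf}")
        lines.append(f"conditional[{i}].effect = {snp.effect}")
    Path(path).write_text("\n".join(lines) + "\n")
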