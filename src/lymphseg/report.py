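"""Automated structured-report content and N-staging.

The report carries exactly what a radiology structured report records for
pelvic nodal status: the number of suspicious nodes (short diameter
strictly > 0.8 cm by default), the short diameter and volume of the
largest node, and the resulting N-stage — N1 if at least one suspicious
node is present, N0 otherwise.  The largest-node fields are populated from
the largest segmented node even when none exceeds the cutoff, and are
absent only when no node was segmented at all.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional

from .lesions import LesionSet, filter_suspicious, largest_lesion

__all__ = ["StructuredReport", "build_report", "render_report", "parse_report"]


@dataclass(frozen=True)
class StructuredReport:
    n_suspicious: int
    largest_short_diameter_cm: Optional[float]
    largest_volume_cm3: Optional[float]
    n_stage: str                 # "N0" | "N1"
    cutoff_cm: float

    def __post_init__(self) -> None:
        if self.n_stage not in ("N0", "N1"):
            raise ValueError(f"n_stage must be 'N0' or 'N1', got {self.n_stage}")
        if (self.n_stage == "N1") != (self.n_suspicious >= 1):
            raise ValueError("n_stage must be N1 iff n_suspicious >= 1")


def build_report(lesion_set: LesionSet, cutoff_cm: float = 0.8) -> StructuredReport:
    """Summarize a measured lesion set into the structured report."""
    suspicious = filter_suspicious(lesion_set, cutoff_cm)
    largest = largest_lesion(lesion_set)
    return StructuredReport(
        n_suspicious=len(suspicious),
        largest_short_diameter_cm=(
            largest.short_diameter_cm if largest is not None else None
        ),
        largest_volume_cm3=largest.volume_cm3 if largest is not None else None,
        n_stage="N1" if suspicious else "N0",
        cutoff_cm=cutoff_cm,
    )


def render_report(report: StructuredReport, format: str = "json") -> str:
    """Serialize a report to deterministic JSON or human-readable text."""
    if format == "json":
        return json.dumps(
            {
                "n_suspicious": report.n_suspicious,
                "largest_short_diameter_cm": report.largest_short_diameter_cm,
                "largest_volume_cm3": report.largest_volume_cm3,
                "n_stage": report.n_stage,
                "cutoff_cm": report.cutoff_cm,
            },
            indent=2,
            sort_keys=True,
        )
    if format == "text":
        lines = [
            "Pelvic lymph node structured report",
            f"Suspicious nodes (short diameter > {report.cutoff_cm:g} cm): "
            f"{report.n_suspicious}",
        ]
        if report.largest_short_diameter_cm is not None:
            lines.append(
                f"Largest node: short diameter "
                f"{report.largest_short_diameter_cm:.2f} cm, volume "
                f"{report.largest_volume_cm3:.3f} cm3"
            )
        else:
            lines.append("Largest node: none segmented")
        lines.append(f"N-stage: {report.n_stage}")
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown format: {format!r}")


def parse_report(serialized: str) -> StructuredReport:
    """Inverse of ``render_report(..., format='json')``."""
    d = json.loads(serialized)
    return StructuredReport(
        n_suspicious=d["n_suspicious"],
        largest_short_diameter_cm=d["largest_short_diameter_cm"],
        largest_volume_cm3=d["largest_volume_cm3"],
        n_stage=d["n_stage"],
        cutoff_cm=d["cutoff_cm"],
    )
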