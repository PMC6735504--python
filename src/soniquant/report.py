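"""Human- and machine-readable run reports.

Assembles whatever analysis products exist — sonication summaries, ROI
concentration tables, growth fits, survival metrics — into a plain-text
summary and a JSON document with deterministic ordering; sections whose
inputs are absent are omitted cleanly.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

from .relaxometry import RoiComparison

__all__ = ["write_report", "build_report"]


def _round_floats(obj, ndigits: int = 6):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def build_report(
    sonication_summary: dict | None = None,
    roi_comparisons: Sequence[RoiComparison] | None = None,
    growth: dict | None = None,
    survival: dict | None = None,
    concentrations: dict | None = None,
    headline: dict | None = None,
) -> tuple[str, dict]:
    """Assemble report text and JSON dict from available sections."""
    doc: dict = {}
    lines: list[str] = ["soniquant run report", "=" * 20]

    if sonication_summary is not None:
        doc["sonication"] = sonication_summary
        lines.append("\n[sonication]")
        for key in sorted(sonication_summary):
            lines.append(f"  {key}: {sonication_summary[key]}")

    if roi_comparisons:
        doc["roi_comparisons"] = [
            {
                "structure": c.structure_label,
                "mean_r1_sonicated": c.mean_r1_sonicated,
                "mean_r1_contralateral": c.mean_r1_contralateral,
                "delta_r1_per_s": c.delta_r1,
                "concentration_mm": c.concentration_mm,
                "concentration_ug_per_g": c.concentration_ug_per_g,
                "n_voxels": c.n_voxels,
            }
            for c in roi_comparisons
        ]
        lines.append("\n[roi delta-R1 / gadolinium]")
        for c in roi_comparisons:
            lines.append(
                f"  {c.structure_label}: dR1={c.delta_r1:.4f} /s  "
                f"[Gd]={c.concentration_mm:.4f} mM ({c.concentration_ug_per_g:.2f} ug/g, "
                f"n={c.n_voxels})"
            )

    for name, section in (
        ("growth", growth),
        ("survival", survival),
        ("concentrations", concentrations),
        ("headline_ratios", headline),
    ):
        if section is not None:
            doc[name] = section
            lines.append(f"\n[{name}]")
            for key in sorted(section):
                lines.append(f"  {key}: {section[key]}")

    doc = _round_floats(doc)
    return "\n".join(lines) + "\n", doc


def write_report(path_prefix: str | Path, **sections) -> tuple[Path, Path]:
    """Write ``<prefix>.txt`` and ``<prefix>.json``; byte-deterministic
    for identical inputs. Returns the two paths."""
    text, doc = build_report(**sections)
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    txt_path = prefix.with_suffix(".txt")
    json_path = prefix.with_suffix(".json")
    txt_path.write_text(text)
    json_path.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
    return txt_path, json_path
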