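"""Nested pie-chart rendering of double digest maps as SVG.

A solved map is drawn as three concentric rings sharing the molecule's
total length L: the A-digest outermost, the B-digest in the middle and the
double digest innermost (configurable).  Arc lengths are proportional to
fragment lengths, read clockwise from twelve o'clock by default.
Zero-length fragments — coincident cut sites introduced by padding — have no
arc, so they are drawn as labeled radial ticks.  Output is deterministic for
a fixed spec.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from . import core
from .core import DDPInstance, DigestMapError, SolutionRecord

__all__ = ["ChartSpec", "render_chart"]

_PALETTE = (
    "#4e79a7", "#f28e2b", "#59a14f", "#e15759", "#76b7b2",
    "#edc948", "#b07aa1", "#ff9da7", "#9c755f", "#bab0ac",
)


@dataclass
class ChartSpec:
    solution: SolutionRecord
    instance: DDPInstance
    ring_order: tuple = ("a", "b", "c")  # outermost first
    start_angle: float = 0.0  # degrees clockwise from twelve o'clock
    label_zero: bool = True
    approximate: bool = False  # allow rendering non-exact solutions

    def rings(self) -> dict:
        inst = core.pad_to_canonical(self.instance)
        return {
            "a": core.permute(inst.a, self.solution.mu),
            "b": core.permute(inst.b, self.solution.nu),
            "c": self.solution.dds,
        }


def _polar(cx, cy, r, angle_deg):
    # 0 deg at twelve o'clock, increasing clockwise
    rad = math.radians(angle_deg - 90.0)
    return cx + r * math.cos(rad), cy + r * math.sin(rad)


def _annular_sector(cx, cy, r_in, r_out, a0, a1):
    large = 1 if (a1 - a0) % 360 > 180 else 0
    x0, y0 = _polar(cx, cy, r_out, a0)
    x1, y1 = _polar(cx, cy, r_out, a1)
    x2, y2 = _polar(cx, cy, r_in, a1)
    x3, y3 = _polar(cx, cy, r_in, a0)
    return (
        f"M {x0:.3f} {y0:.3f} "
        f"A {r_out:.3f} {r_out:.3f} 0 {large} 1 {x1:.3f} {y1:.3f} "
        f"L {x2:.3f} {y2:.3f} "
        f"A {r_in:.3f} {r_in:.3f} 0 {large} 0 {x3:.3f} {y3:.3f} Z"
    )


def render_chart(spec: ChartSpec, path) -> None:
    """Write the nested pie chart of a solution to an SVG file."""
    if spec.solution.fitness != 1.0 and not spec.approximate:
        raise DigestMapError(
            "refusing to draw a non-exact solution; set approximate=True to override"
        )
    rings = spec.rings()
    totals = {k: sum(v) for k, v in rings.items()}
    if len(set(totals.values())) != 1:
        raise DigestMapError(f"ring totals disagree: {totals}")
    L = totals["a"]

    size = 420.0
    cx = cy = size / 2
    width = 44.0
    gap = 8.0
    r_out = size / 2 - 10.0
    parts = [f'<svg xmlns="http://www.w3.org/2000/svg" width="{size:.0f}" height="{size:.0f}" '
             f'viewBox="0 0 {size:.0f} {size:.0f}">']
    parts.append(f'<!-- total length L = {L} ; rings outer-to-inner: '
                 f'{", ".join(spec.ring_order)} -->')
    for ridx, key in enumerate(spec.ring_order):
        frags = rings[key]
        ro = r_out - ridx * (width + gap)
        ri = ro - width
        angle = spec.start_angle
        for fidx, frag in enumerate(frags):
            sweep = 360.0 * frag / L
            color = _PALETTE[fidx % len(_PALETTE)]
            if frag == 0:
                if spec.label_zero:
                    x0, y0 = _polar(cx, cy, ri - 4, angle)
                    x1, y1 = _polar(cx, cy, ro + 4, angle)
                    parts.append(
                        f'<line x1="{x0:.3f}" y1="{y0:.3f}" x2="{x1:.3f}" y2="{y1:.3f}" '
                        f'stroke="#333333" stroke-width="1.5" stroke-dasharray="3 2" '
                        f'class="zero-tick"/>'
                    )
                    xt, yt = _polar(cx, cy, ro + 9, angle)
                    parts.append(
                        f'<text x="{xt:.3f}" y="{yt:.3f}" font-size="8" '
                        f'text-anchor="middle">0</text>'
                    )
                continue
            d = _annular_sector(cx, cy, ri, ro, angle, angle + sweep)
            parts.append(
                f'<path d="{d}" fill="{color}" stroke="#ffffff" stroke-width="1" '
                f'class="ring-{key}"/>'
            )
            xm, ym = _polar(cx, cy, (ri + ro) / 2, angle + sweep / 2)
            parts.append(
                f'<text x="{xm:.3f}" y="{ym:.3f}" font-size="10" text-anchor="middle" '
                f'dominant-baseline="middle">{frag}</text>'
            )
            angle += sweep
    parts.append(f'<text x="{cx:.3f}" y="{cy:.3f}" font-size="12" text-anchor="middle" '
                 f'dominant-baseline="middle">L={L}</text>')
    parts.append("</svg>")
    with open(path, "w") as fh:
        fh.write("\n".join(parts) + "\n")
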