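"""Chart formalism: correlation/hazard bar panels ordered by longitudinal
slope, with open bars for irrelevant cells and two red delimiters
separating significant down-, no- and uptrends.

Rendering is optional and isolated behind the :class:`ChartSpec` boundary;
tests assert on the spec, not pixels.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from enum import Enum
from typing import Mapping

from .data_model import Sex
from .errors import ChartSpecError
from .trends import TrendOrdering

__all__ = ["PanelKind", "ChartBar", "ChartSpec", "build_chart_spec", "render_chart"]


class PanelKind(str, Enum):
    lifespan_correlation = "lifespan_correlation"
    cox_display = "cox_display"


@dataclass(frozen=True)
class ChartBar:
    feature: str
    value: float
    filled: bool


@dataclass(frozen=True)
class ChartSpec:
    sex: Sex | None
    dataset_label: str
    bars: tuple
    delimiters: tuple  # (delimiter_down, delimiter_up)
    panel_kind: PanelKind

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sex"] = None if self.sex is None else self.sex.value
        d["panel_kind"] = self.panel_kind.value
        d["bars"] = [dataclasses.asdict(b) for b in self.bars]
        d["delimiters"] = list(self.delimiters)
        return d


def build_chart_spec(ordering: TrendOrdering, cells: Mapping[str, tuple],
                     panel_kind, dataset_label: str = "") -> ChartSpec:
    """Assemble a chart spec from a trend ordering and per-feature cells.

    ``cells`` maps feature → ``(value, relevant)``.  For hazard panels the
    value is the raw coefficient and the y-axis is inverted here
    (``bar = -coefficient``) so both panel kinds read the same way.
    """
    panel_kind = PanelKind(panel_kind)
    ordered = set(ordering.ordered_features)
    given = set(cells)
    if ordered != given:
        diff = sorted(ordered.symmetric_difference(given))
        raise ChartSpecError(
            "ordering and cells disagree on features: " + ", ".join(diff)
        )
    bars = []
    for feature in ordering.ordered_features:
        value, relevant = cells[feature]
        if panel_kind is PanelKind.cox_display:
            value = -value
        bars.append(ChartBar(feature=feature, value=float(value),
                             filled=bool(relevant)))
    return ChartSpec(
        sex=ordering.sex,
        dataset_label=dataset_label,
        bars=tuple(bars),
        delimiters=(ordering.delimiter_down, ordering.delimiter_up),
        panel_kind=panel_kind,
    )


def render_chart(spec: ChartSpec, path) -> None:
    """Render the bar panel to an image file (matplotlib, headless)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(max(6, 0.4 * len(spec.bars)), 4))
    xs = range(len(spec.bars))
    for x, bar in zip(xs, spec.bars):
        if bar.filled:
            ax.bar(x, bar.value, color="steelblue", edgecolor="black")
        else:
            ax.bar(x, bar.value, color="none", edgecolor="black")
    for d in spec.delimiters:
        ax.axvline(d - 0.5, color="red", linewidth=1.5)
    ax.set_xticks(list(xs))
    ax.set_xticklabels([b.feature for b in spec.bars], rotation=90, fontsize=7)
    ax.axhline(0, color="black", linewidth=0.8)
    label = ("lifespan correlation" if spec.panel_kind is PanelKind.lifespan_correlation
             else "inverted hazard coefficient")
    sex = "" if spec.sex is None else f" ({spec.sex.value})"
    ax.set_ylabel(label)
    ax.set_title(f"{spec.dataset_label}{sex}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
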