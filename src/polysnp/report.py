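"""Stage-by-stage attrition accounting.

Every filtering stage records how many items it removed against an explicit
denominator, so reports can be rendered in the narrative style
"N removed (P%)" with thousands separators.  Percentages are rounded to the
nearest integer, except below 2% where one decimal is kept so small classes
do not vanish to "0%".
"""

from __future__ import annotations

from dataclasses import dataclass


def format_percent(removed: int, denominator: int) -> str:
    if denominator <= 0:
        return "0.0"
    pct = 100.0 * removed / denominator
    if pct < 2.0:
        return f"{round(pct, 1):.1f}"
    return f"{round(pct):d}"


def format_count(n: int) -> str:
    return f"{n:,}"


@dataclass(frozen=True)
class AttritionStage:
    name: str
    denominator: int
    removed: int
    remaining: int

    def __post_init__(self) -> None:
        if self.removed < 0 or self.remaining < 0:
            raise ValueError(f"stage {self.name!r}: negative count")

    @property
    def percent(self) -> str:
        return format_percent(self.removed, self.denominator)

    def render(self) -> str:
        return f"{format_count(self.removed)} ({self.percent}%)"


class AttritionReport:
    """Ordered per-stage (removed, remaining, percent) accounting."""

    def __init__(self, title: str = "") -> None:
        self.title = title
        self.stages: list[AttritionStage] = []

    def add_stage(self, name: str, denominator: int, removed: int, remaining: int) -> None:
        self.stages.append(AttritionStage(name, denominator, removed, remaining))

    def extend(self, other: "AttritionReport") -> None:
        self.stages.extend(other.stages)

    def to_text(self) -> str:
        lines = []
        if self.title:
            lines.append(self.title)
        for st in self.stages:
            lines.append(
                f"  {st.name}: {st.render()} removed, "
                f"{format_count(st.remaining)} remaining "
                f"of {format_count(st.denominator)}"
            )
        return "\n".join(lines)

    def to_tsv(self) -> str:
        rows = ["stage\tdenominator\tremoved\tremaining\tpercent"]
        for st in self.stages:
            rows.append(
                f"{st.name}\t{st.denominator}\t{st.removed}\t{st.remaining}\t{st.percent}"
            )
        return "\n".join(rows) + "\n"
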