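"""Karyotype notation: integer chromosome copies <-> strings like ``47,XY,+21``.

The rendered form is ``total,SEX[,+N...][,-N...]`` where *total* counts whole
chromosomes (44 autosomes in a disomic baseline, plus sex chromosomes, plus
gains minus losses) and SEX is written ``XX``/``XY``/``XO`` (single X, no Y;
the clinical shorthand rather than ISCN ``45,X``), extensible to ``XXY`` etc.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

AUTOSOMES = tuple(f"chr{i}" for i in range(1, 23))
CHROM_ORDER = AUTOSOMES + ("chrX", "chrY")


def _chrom_number(chrom: str) -> int:
    return int(chrom.removeprefix("chr"))


def render_sex(x_copies: int, y_copies: int) -> str:
    if x_copies <= 0 and y_copies <= 0:
        raise ValueError("no sex chromosome present")
    if x_copies == 1 and y_copies == 0:
        return "XO"
    return "X" * x_copies + "Y" * y_copies


def render_karyotype(
    x_copies: int,
    y_copies: int,
    gains: tuple[str, ...] = (),
    losses: tuple[str, ...] = (),
) -> str:
    """Render a karyotype string from sex-chromosome copies and autosomal events."""
    total = 44 + x_copies + y_copies + len(gains) - len(losses)
    parts = [str(total), render_sex(x_copies, y_copies)]
    parts += [f"+{_chrom_number(c)}" for c in sorted(gains, key=_chrom_number)]
    parts += [f"-{_chrom_number(c)}" for c in sorted(losses, key=_chrom_number)]
    return ",".join(parts)


@dataclass
class Karyotype:
    """Whole-chromosome integer copy numbers plus sex-chromosome composition.

    ``autosome_copies`` is sparse: any autosome not listed has the disomic
    default of 2.  Mosaic (non-integer) states are out of scope.
    """

    autosome_copies: dict[str, int] = field(default_factory=dict)
    x_copies: int = 2
    y_copies: int = 0

    def __post_init__(self) -> None:
        for chrom, n in self.autosome_copies.items():
            if not isinstance(n, int) or n < 0:
                raise ValueError(f"copy number for {chrom} must be a non-negative int")
        if self.x_copies < 0 or self.y_copies < 0:
            raise ValueError("sex-chromosome copies must be non-negative")
        # unlisted autosomes default to 2 copies, so an all-zero karyotype can
        # only arise when every autosome is explicitly zeroed
        if (
            self.x_copies == 0
            and self.y_copies == 0
            and len(self.autosome_copies) == 22
            and all(v == 0 for v in self.autosome_copies.values())
        ):
            raise ValueError("karyotype has no chromosome with positive copy number")

    def copy_of(self, chrom: str) -> int:
        if chrom in ("chrX", "X"):
            return self.x_copies
        if chrom in ("chrY", "Y"):
            return self.y_copies
        return self.autosome_copies.get(chrom, 2)

    @property
    def gains(self) -> tuple[str, ...]:
        return tuple(c for c, n in self.autosome_copies.items() if n > 2)

    @property
    def losses(self) -> tuple[str, ...]:
        return tuple(c for c, n in self.autosome_copies.items() if n < 2)

    def to_string(self) -> str:
        return render_karyotype(self.x_copies, self.y_copies, self.gains, self.losses)

    @classmethod
    def from_string(cls, text: str) -> "Karyotype":
        """Parse e.g. ``46,XX``, ``45,XO``, ``47,XY,+21`` back into copies."""
        parts = [p.strip() for p in text.split(",")]
        if len(parts) < 2:
            raise ValueError(f"not a karyotype string: {text!r}")
        total = int(parts[0])
        sex = parts[1]
        if sex == "XO":
            x, y = 1, 0
        elif sex and re.fullmatch(r"X*Y*", sex):
            x, y = sex.count("X"), sex.count("Y")
        else:
            raise ValueError(f"unrecognized sex designation {sex!r} in {text!r}")
        autosomes: dict[str, int] = {}
        for ev in parts[2:]:
            m = re.fullmatch(r"([+-])(\d+)", ev)
            if not m:
                raise ValueError(f"unrecognized event {ev!r} in {text!r}")
            chrom = f"chr{m.group(2)}"
            autosomes[chrom] = 3 if m.group(1) == "+" else 1
        expected = 44 + x + y + sum(n - 2 for n in autosomes.values())
        if total != expected:
            raise ValueError(
                f"total {total} inconsistent with events in {text!r} "
                f"(expected {expected})"
            )
        return cls(autosome_copies=autosomes, x_copies=x, y_copies=y)


# The five karyotypes used throughout the study's sample panel.
PANEL = ("46,XX", "46,XY", "45,XO", "47,XY,+21", "47,XY,+18")
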