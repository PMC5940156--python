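"""Reference-normalized modified Z-score aneuploidy calling.

Each chromosome's *relative copy number* is its share of the sample's UA
reads divided by the same share in a known normal-male reference:

    ratio_c = (sample_c / sample_total) / (reference_c / reference_total)

For a disomic autosome against the diploid reference the ratio is ~1; a
trisomy gives ~1.5 (slightly less, because the extra chromosome inflates the
sample total -- the closure effect), a monosomy ~0.5.  The modified Z-score
scales the deviation by the empirical standard deviation of normal autosomal
ratios:

    z_c = (ratio_c - expected_c) / sd_normal          (sd_normal = 0.0897)

and a chromosome is called a gain at z >= z_threshold, a loss at
z <= -z_threshold (default threshold 3.5, the conventional modified-Z
cutoff).  Sex chromosomes are translated to copy numbers by rounding their
ratios against the single-X, single-Y male reference, with a Y-presence
cutoff separating XO/XX from Y-bearing karyotypes.  Polyploidies that
preserve all ratios (e.g. 69,XXX vs 46,XX) are invisible to this method, as
are satellite/heteromorphism expansions, which ultra-low-coverage counting
cannot see.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .align_count import ChromCounts
from .karyotype import render_karyotype, render_sex

logger = logging.getLogger(__name__)

#: Empirical standard deviation of normal autosomal ratios (n = 219 in the
#: calibration set this default was taken from).
SD_NORMAL = 0.0897

GAIN = "gain"
LOSS = "loss"
NORMAL = "normal"


@dataclass
class CallerConfig:
    reference_counts: ChromCounts
    sd_normal: float = SD_NORMAL
    z_threshold: float = 3.5
    y_presence_ratio: float = 0.3

    def __post_init__(self) -> None:
        if self.sd_normal <= 0:
            raise ValueError("sd_normal must be positive")
        if self.z_threshold <= 0:
            raise ValueError("z_threshold must be positive")
        ref = self.reference_counts.counts
        y_key = _find_key(ref, "chrY")
        if y_key is None or ref[y_key] <= 0:
            raise ValueError(
                "reference must be a normal male (chrY count > 0 required)"
            )


@dataclass
class ChromCall:
    chrom: str
    ua_count: float
    ratio: float
    z: float
    call: str  # normal | gain | loss
    flag: str = ""


@dataclass
class KaryotypeCall:
    sample_id: str
    total_count: int
    sex_string: str
    autosomal_events: list[tuple[str, str]] = field(default_factory=list)
    rendered: str = ""
    chrom_calls: list[ChromCall] = field(default_factory=list)
    n_ua_used: int = 0
    flags: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (c.chrom, c.ua_count, c.ratio, c.z, c.call, c.flag)
                for c in self.chrom_calls
            ],
            columns=["chrom", "ua_count", "ratio", "z", "call", "flag"],
        )

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "karyotype": self.rendered,
            "n_ua_used": self.n_ua_used,
            "flags": self.flags,
        }


def _find_key(counts: dict, name: str) -> str | None:
    for key in (name, name.removeprefix("chr")):
        if key in counts:
            return key
    return None


def _is_sex_chrom(chrom: str) -> bool:
    return chrom in ("chrX", "chrY", "X", "Y")


def relative_copy_number(
    sample: ChromCounts, reference: ChromCounts
) -> dict[str, float]:
    """Per-chromosome ratio of sample read share to reference read share."""
    s_total = sample.total
    r_total = reference.total
    if s_total <= 0 or r_total <= 0:
        raise ValueError("sample and reference counts must be non-empty")
    ratios: dict[str, float] = {}
    for chrom, r_count in reference.counts.items():
        if r_count <= 0:
            raise ValueError(
                f"reference count for {chrom} is zero; cannot normalize"
            )
        s_count = sample.counts.get(chrom, 0)
        ratios[chrom] = (s_count / s_total) / (r_count / r_total)
    return ratios


def modified_z(ratio: float, expected_ratio: float, cfg: CallerConfig) -> float:
    """Deviation of the ratio from expectation in units of sd_normal."""
    return (ratio - expected_ratio) / cfg.sd_normal


def classify_chromosome(z: float, cfg: CallerConfig) -> str:
    if z >= cfg.z_threshold:
        return GAIN
    if z <= -cfg.z_threshold:
        return LOSS
    return NORMAL


def sex_karyotype(
    ratio_x: float, ratio_y: float, cfg: CallerConfig
) -> tuple[int, int, str]:
    """Round sex-chromosome ratios (vs. a 1X/1Y male reference) to copy numbers.

    chrY is declared absent below ``y_presence_ratio``; present chromosomes
    round to the nearest copy number (at least one).  A sample with no sex
    chromosome at all is an error (likely an upstream failure).
    """
    y_copies = 0 if ratio_y < cfg.y_presence_ratio else max(1, round(ratio_y))
    if y_copies == 0 and ratio_x < cfg.y_presence_ratio:
        raise ValueError(
            f"no sex chromosome detected (ratio_X={ratio_x:.3f}, "
            f"ratio_Y={ratio_y:.3f})"
        )
    x_floor = 1 if y_copies == 0 else 0
    x_copies = max(round(ratio_x), x_floor)
    return x_copies, y_copies, render_sex(x_copies, y_copies)


def karyotype_string(
    autosomal_calls: dict[str, str], x_copies: int, y_copies: int
) -> str:
    """Render e.g. ``47,XY,+21`` from per-autosome calls and sex copies."""
    gains = tuple(c for c, call in autosomal_calls.items() if call == GAIN)
    losses = tuple(c for c, call in autosomal_calls.items() if call == LOSS)
    return render_karyotype(x_copies, y_copies, gains, losses)


def call_sample(sample: ChromCounts, cfg: CallerConfig) -> KaryotypeCall:
    """Full per-sample call: ratios, Z-scores, classes and karyotype string."""
    reference = cfg.reference_counts
    ratios = relative_copy_number(sample, reference)
    chrom_calls: list[ChromCall] = []
    autosomal: dict[str, str] = {}
    flags: list[str] = []
    ratio_x = ratio_y = 0.0
    for chrom, ratio in ratios.items():
        count = sample.counts.get(chrom, 0)
        if _is_sex_chrom(chrom):
            if chrom in ("chrX", "X"):
                ratio_x = ratio
            else:
                ratio_y = ratio
            chrom_calls.append(
                ChromCall(chrom, count, ratio, float("nan"), "sex", "")
            )
            continue
        z = modified_z(ratio, 1.0, cfg)
        call = classify_chromosome(z, cfg)
        flag = ""
        if count == 0:
            flag = "zero_count"
            flags.append(f"{chrom}: zero UA count (possible upstream failure)")
            logger.warning(
                "sample %s: %s has zero UA reads but nonzero reference count",
                sample.sample_id,
                chrom,
            )
        autosomal[chrom] = call
        chrom_calls.append(ChromCall(chrom, count, ratio, z, call, flag))
    x_copies, y_copies, sex = sex_karyotype(ratio_x, ratio_y, cfg)
    rendered = karyotype_string(autosomal, x_copies, y_copies)
    gains = [(c, GAIN) for c, v in autosomal.items() if v == GAIN]
    losses = [(c, LOSS) for c, v in autosomal.items() if v == LOSS]
    total = 44 + x_copies + y_copies + len(gains) - len(losses)
    return KaryotypeCall(
        sample_id=sample.sample_id,
        total_count=total,
        sex_string=sex,
        autosomal_events=gains + losses,
        rendered=rendered,
        chrom_calls=chrom_calls,
        n_ua_used=sample.n_ua_used,
        flags=flags,
    )


def recalibrate_sd(
    normal_samples: list[ChromCounts], reference: ChromCounts
) -> tuple[float, int]:
    """Standard deviation of autosomal ratios across known-normal samples.

    Returns (sd, n) where n is the number of autosomal ratio observations
    pooled.  Provided for recalibration against a user's own normals; the
    shipped default sd_normal is not changed by this routine.
    """
    import numpy as np

    values = []
    for sample in normal_samples:
        ratios = relative_copy_number(sample, reference)
        values.extend(v for c, v in ratios.items() if not _is_sex_chrom(c))
    if len(values) < 2:
        raise ValueError("need at least two autosomal ratio observations")
    return float(np.std(values, ddof=1)), len(values)
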