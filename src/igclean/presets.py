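"""Ready-made run configurations for the published tag and primer sets."""

from __future__ import annotations

from .midtags import BASIC_MID_SET
from .seqio import CleanConfig

#: Human heavy-chain variable-region primers (5'->3', IUPAC degenerate).
HUMAN_HEAVY_FORWARD_PRIMERS: tuple[str, ...] = (
    "TGCGMCAGGCCCCYGGACAAR",
    "ARGRAAGGCCCTGGAGTGG",
    "CCGCCAGGCTCCAGGSAAG",
    "MGGGAAGGGRCTGGAGTGG",
    "GAAAGGCCTGGAGTGGATGGG",
    "TTGAGTGGCTGGGRAGGAC",
)
HUMAN_HEAVY_REVERSE_PRIMERS: tuple[str, ...] = ("TGACCRKGGTHCCYTGGCCC",)


def human_heavy_config(
    quality_threshold: float = 20,
    max_mismatches: int = 2,
    primer_fraction: float = 0.75,
    search_range: int = 50,
    min_mid_len: int = 5,
    sample_table: dict[tuple[int, int], str] | None = None,
) -> CleanConfig:
    """A human heavy-chain cleaning run with the basic nine-tag set.

    Defaults follow the validated run parameters: average quality
    threshold 20, two allowed primer mismatches, 75% primer fraction,
    50-nt end windows, 5-nt minimal tag length, raw length 200-400 and
    gene length 150-360.  The default sample table maps three forward/
    reverse tag combinations to samples s1-s3.
    """
    if sample_table is None:
        sample_table = {(1, 2): "s1", (3, 4): "s2", (5, 6): "s3"}
    return CleanConfig(
        organism="Human",
        chain="h",
        quality_threshold=quality_threshold,
        max_mismatches=max_mismatches,
        primer_fraction=primer_fraction,
        search_range=search_range,
        min_mid_len=min_mid_len,
        mids=list(BASIC_MID_SET),
        forward_primers=list(HUMAN_HEAVY_FORWARD_PRIMERS),
        reverse_primers=list(HUMAN_HEAVY_REVERSE_PRIMERS),
        min_l1=200,
        max_l1=400,
        min_l2=150,
        max_l2=360,
        sample_table=dict(sample_table),
    )
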