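"""Cell-cycle stage vocabulary shared across the pipeline."""

from __future__ import annotations

#: canonical stage order through one cycle
STAGES: tuple[str, ...] = (
    "G1",
    "S",
    "G2",
    "prophase",
    "metaphase",
    "anaphase_telophase",
    "cytokinesis",
)

INTERPHASE_STAGES: frozenset[str] = frozenset({"G1", "S", "G2"})
MITOTIC_STAGES: frozenset[str] = frozenset(
    {"prophase", "metaphase", "anaphase_telophase", "cytokinesis"}
)


def validate_stage(stage: str) -> str:
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; expected one of {STAGES}")
    return stage
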