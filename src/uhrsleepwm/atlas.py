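"""Canonical JHU ICBM-DTI-81 white-matter tract labels (48 regions).

The ROI FA tables consumed by this package carry one column per tract of the
John Hopkins University white-matter atlas.  The canonical label list is
shipped as a packaged text file and every input table is validated against it
(exact match after whitespace normalization), so that downstream code can rely
on column identity — in particular the three callosal segments used for the
corpus-callosum summary.
"""

from __future__ import annotations

from importlib import resources

__all__ = [
    "JHU_LABELS",
    "CALLOSAL_LABELS",
    "N_ROIS",
    "normalize_label",
    "validate_labels",
]


def _load_labels() -> tuple[str, ...]:
    text = (
        resources.files("uhrsleepwm")
        .joinpath("data/jhu_icbm_dti81_labels.txt")
        .read_text(encoding="utf-8")
    )
    labels = tuple(line.strip() for line in text.splitlines() if line.strip())
    if len(labels) != 48:
        raise RuntimeError(f"packaged atlas list has {len(labels)} labels, expected 48")
    return labels


JHU_LABELS: tuple[str, ...] = _load_labels()

CALLOSAL_LABELS: tuple[str, str, str] = (
    "Genu of corpus callosum",
    "Body of corpus callosum",
    "Splenium of corpus callosum",
)

N_ROIS: int = len(JHU_LABELS)


def normalize_label(label: str) -> str:
    """Collapse internal whitespace and strip; labels are otherwise exact."""
    return " ".join(str(label).split())


def validate_labels(columns) -> list[str]:
    """Check that *columns* are exactly the 48 atlas labels (any order).

    Returns the normalized column names in their input order.  Raises
    ``ValueError`` naming missing and unexpected labels.
    """
    normalized = [normalize_label(c) for c in columns]
    got = set(normalized)
    expected = set(JHU_LABELS)
    missing = sorted(expected - got)
    extra = sorted(got - expected)
    if missing or extra:
        parts = []
        if missing:
            parts.append(f"missing ROI labels: {missing}")
        if extra:
            parts.append(f"unexpected labels: {extra}")
        raise ValueError("; ".join(parts))
    if len(normalized) != len(got):
        raise ValueError("duplicate ROI labels in table")
    return normalized
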