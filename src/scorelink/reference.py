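"""Reference item-parameter sets used throughout the analyses and tests.

Two published graded-response parameter sets for the six-item BSI Depression
subscale are included, both on the PROMIS Depression metric: one obtained by
anchoring on the PROMIS Depression 8a short form, one by anchoring on an
18-item PROMIS Depression set.  Items use the BSI 5-point bother scale
(0 = "not at all" ... 4 = "extremely"), so each item carries one slope and
four thresholds.

The official PROMIS Depression item parameters are not redistributable here,
so :func:`default_anchor_bank` provides a documented synthetic bank of
plausible 5-category anchor items (slopes 1.5-3.5, spread thresholds) for
simulation fixtures; it defines a realistic anchor metric, not the PROMIS
bank itself.
"""

from __future__ import annotations

from .grm import GRMItem

__all__ = [
    "bsi_items_8a_linked",
    "bsi_items_18item_linked",
    "default_anchor_bank",
]

# Published BSI Depression GRM parameters linked via the PROMIS Depression 8a
# short form: (slope, b1..b4) per item.
_BSI_8A = {
    "BSI_D1": (1.47, (-0.02, 1.33, 2.31, 3.32)),
    "BSI_D2": (1.99, (-0.29, 0.82, 1.45, 2.33)),
    "BSI_D3": (2.38, (0.10, 1.15, 2.00, 2.73)),
    "BSI_D4": (3.70, (0.79, 1.51, 1.85, 2.54)),
    "BSI_D5": (2.68, (0.55, 1.43, 1.97, 2.48)),
    "BSI_D6": (2.41, (1.78, 2.48, 2.72, 3.06)),
}

# Same items linked via the 18-item PROMIS Depression set.
_BSI_18 = {
    "BSI_D1": (1.48, (0.01, 1.34, 2.31, 3.31)),
    "BSI_D2": (2.08, (-0.24, 0.82, 1.43, 2.29)),
    "BSI_D3": (2.42, (0.12, 1.14, 1.98, 2.71)),
    "BSI_D4": (3.78, (0.79, 1.51, 1.84, 2.54)),
    "BSI_D5": (2.67, (0.56, 1.44, 1.98, 2.49)),
    "BSI_D6": (2.31, (1.82, 2.54, 2.79, 3.14)),
}

# Synthetic anchor bank: 18 five-category items with slopes in [1.5, 3.5] and
# thresholds spread over the severity range a depression bank targets.  The
# first eight emulate a short form.
_ANCHOR = [
    (2.50, (-1.2, -0.2, 0.8, 1.8)),
    (3.00, (-0.8, 0.0, 0.9, 2.0)),
    (1.80, (-1.5, -0.5, 0.6, 1.7)),
    (2.20, (-0.6, 0.3, 1.2, 2.2)),
    (3.40, (-1.0, -0.1, 0.7, 1.6)),
    (1.60, (-1.8, -0.7, 0.4, 1.5)),
    (2.80, (-0.4, 0.5, 1.4, 2.4)),
    (2.00, (-1.4, -0.3, 0.8, 2.1)),
    (2.60, (-0.9, 0.1, 1.0, 1.9)),
    (3.20, (-0.5, 0.4, 1.3, 2.3)),
    (1.90, (-1.6, -0.6, 0.5, 1.6)),
    (2.40, (-0.7, 0.2, 1.1, 2.0)),
    (3.50, (-1.1, -0.2, 0.6, 1.7)),
    (1.50, (-2.0, -0.9, 0.3, 1.4)),
    (2.90, (-0.3, 0.6, 1.5, 2.5)),
    (2.10, (-1.3, -0.4, 0.7, 1.8)),
    (2.70, (-0.8, 0.3, 1.2, 2.1)),
    (3.10, (-0.2, 0.7, 1.6, 2.6)),
]


def _build(params: dict, fixed: bool) -> list[GRMItem]:
    return [
        GRMItem(item_id=name, slope=a, thresholds=b, fixed=fixed)
        for name, (a, b) in params.items()
    ]


def bsi_items_8a_linked(fixed: bool = False) -> list[GRMItem]:
    """The six BSI Depression items as linked through the PROMIS 8a short form."""
    return _build(_BSI_8A, fixed)


def bsi_items_18item_linked(fixed: bool = False) -> list[GRMItem]:
    """The six BSI Depression items as linked through the 18-item PROMIS set."""
    return _build(_BSI_18, fixed)


def default_anchor_bank(n_items: int = 8) -> list[GRMItem]:
    """Synthetic fixed anchor items for simulation fixtures (max 18)."""
    if not 1 <= n_items <= len(_ANCHOR):
        raise ValueError(f"n_items must be in 1..{len(_ANCHOR)}")
    return [
        GRMItem(item_id=f"ANCHOR_{i + 1:02d}", slope=a, thresholds=b, fixed=True)
        for i, (a, b) in enumerate(_ANCHOR[:n_items])
    ]
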