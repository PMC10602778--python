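"""Catalogue of the 48 binary MINI-PLUS comorbidity items.

The MINI-PLUS structured interview yields yes/no disorder indicators; after
removing the schizophrenia-spectrum items, 48 binary entries remain. The
authoritative item list is not public, so this catalogue is a *synthetic*
stand-in: a plausible MINI-PLUS-structured list in which the five items with
published indices and labels are pinned to their printed positions --

  C1  major depressive episode: current
  C2  major depressive episode: recurrent
  C8  major depressive episode with melancholic features: recurrent
  C11 suicidality: current
  C40 substance abuse: past 12 months

-- and the remainder follows the MINI-PLUS module structure (mood,
suicidality, anxiety, eating, somatoform, alcohol, substance, other).
Labels are configurable downstream; only the count (48) and the five pinned
indices are load-bearing.
"""

from __future__ import annotations

# category -> list of (1-based item index, label)
MINI_CATEGORIES: dict[str, list[tuple[int, str]]] = {
    "mood": [
        (1, "major depressive episode: current"),
        (2, "major depressive episode: recurrent"),
        (3, "major depressive episode: past"),
        (4, "major depressive episode with melancholic features: current"),
        (5, "dysthymia: current"),
        (6, "dysthymia: past"),
        (7, "hypomanic episode: current"),
        (8, "major depressive episode with melancholic features: recurrent"),
        (9, "manic episode: current"),
        (10, "manic episode: past"),
    ],
    "suicidality": [
        (11, "suicidality: current"),
        (12, "suicidality: past"),
    ],
    "anxiety": [
        (13, "panic disorder: current"),
        (14, "panic disorder: lifetime"),
        (15, "agoraphobia: current"),
        (16, "social phobia: current"),
        (17, "specific phobia: current"),
        (18, "obsessive-compulsive disorder: current"),
        (19, "posttraumatic stress disorder: current"),
        (20, "posttraumatic stress disorder: past"),
        (21, "generalized anxiety disorder: current"),
        (22, "generalized anxiety disorder: past"),
        (23, "panic disorder with agoraphobia: current"),
        (24, "anxiety disorder due to medical condition"),
        (25, "substance-induced anxiety disorder"),
    ],
    "eating": [
        (26, "anorexia nervosa: current"),
        (27, "anorexia nervosa: past"),
        (28, "bulimia nervosa: current"),
        (29, "bulimia nervosa: past"),
    ],
    "somatoform": [
        (30, "somatization disorder: current"),
        (31, "hypochondriasis: current"),
        (32, "body dysmorphic disorder: current"),
        (33, "pain disorder: current"),
        (34, "adjustment disorder: current"),
        (35, "attention-deficit/hyperactivity disorder"),
    ],
    "alcohol": [
        (36, "alcohol dependence: past 12 months"),
        (37, "alcohol abuse: past 12 months"),
        (38, "alcohol dependence: lifetime"),
        (39, "alcohol abuse: lifetime"),
    ],
    "substance": [
        (40, "substance abuse: past 12 months"),
        (41, "substance dependence: past 12 months"),
        (42, "substance dependence: lifetime"),
        (43, "substance abuse: lifetime"),
        (44, "substance-induced mood disorder"),
    ],
    "other": [
        (45, "antisocial personality disorder: lifetime"),
        (46, "conduct disorder: adolescence"),
        (47, "premenstrual dysphoric disorder"),
        (48, "mixed anxiety-depressive disorder"),
    ],
}

N_MINI_ITEMS = 48

#: labels in item order (index 0 -> C1)
MINI_LABELS: list[str] = [""] * N_MINI_ITEMS
#: category of each item, in item order
MINI_ITEM_CATEGORY: list[str] = [""] * N_MINI_ITEMS
for _cat, _items in MINI_CATEGORIES.items():
    for _idx, _label in _items:
        MINI_LABELS[_idx - 1] = _label
        MINI_ITEM_CATEGORY[_idx - 1] = _cat
assert all(MINI_LABELS), "item indices 1..48 must be covered exactly once"

#: pinned indices of the five items named in published group-level results
ITEM_MDE_CURRENT = 1
ITEM_MDE_RECURRENT = 2
ITEM_MDE_MELANCHOLIC_RECURRENT = 8
ITEM_SUICIDALITY_CURRENT = 11
ITEM_SUBSTANCE_ABUSE_12M = 40


def mini_column(i: int) -> str:
    """Column name for 1-based MINI item ``i`` (``mini_01`` .. ``mini_48``)."""
    if not 1 <= i <= N_MINI_ITEMS:
        raise ValueError(f"MINI item index must be in 1..{N_MINI_ITEMS}, got {i}")
    return f"mini_{i:02d}"


MINI_COLUMNS = [mini_column(i) for i in range(1, N_MINI_ITEMS + 1)]
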