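"""Afferent-terminal innervation metrics and the selectivity index.

Lateral-line afferents preferentially contact hair cells of one orientation
(A-to-P or P-to-A flow).  The selectivity index of a terminal is
``100 * (innervated hair cells of the dominant orientation) / (all
innervated hair cells)``: 50 means no selectivity between the two
orientations, 100 means perfect selectivity.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["selectivity_index", "terminal_metrics"]

ORIENTATIONS = ("A-to-P", "P-to-A")


def selectivity_index(counts_by_orientation: dict[str, int] | tuple[int, int]) -> float:
    """Selectivity index from innervated-cell counts per orientation.

    The dominant orientation is the one with the larger count; an exact tie
    gives 50 regardless of which label is called dominant.
    """
    if isinstance(counts_by_orientation, dict):
        counts = list(counts_by_orientation.values())
    else:
        counts = list(counts_by_orientation)
    if any(c < 0 for c in counts):
        raise ValueError("counts must be non-negative")
    total = sum(counts)
    if total == 0:
        raise ValueError("terminal innervates no hair cells")
    return 100.0 * max(counts) / total


def terminal_metrics(
    contacts: pd.DataFrame,
    n_hair_cells_by_orientation: dict[str, int],
) -> pd.DataFrame:
    """Per-terminal innervation metrics from a terminal-cell contact table.

    Parameters
    ----------
    contacts
        One row per terminal-hair-cell contact with columns ``terminal_id``,
        ``terminal_type`` (preferred orientation), ``orientation``,
        ``innervated`` (bool) and ``n_synapses`` (complete synapses on that
        contact).
    n_hair_cells_by_orientation
        Total hair cells of each orientation in the neuromast, used for the
        percent-innervated metric.

    Returns
    -------
    One row per terminal: ``percent_innervated`` (of the neuromast's hair
    cells), ``n_synapses`` and ``selectivity_index``.
    """
    required = {"terminal_id", "terminal_type", "orientation", "innervated", "n_synapses"}
    missing = required - set(contacts.columns)
    if missing:
        raise ValueError(f"contact table lacks columns: {sorted(missing)}")
    if contacts.empty:
        raise ValueError("empty contact table")
    bad = set(contacts["orientation"]) - set(ORIENTATIONS)
    if bad:
        raise ValueError(f"unknown orientation labels: {sorted(bad)}")

    n_total_cells = sum(n_hair_cells_by_orientation.values())
    rows = []
    for tid, grp in contacts.groupby("terminal_id", sort=True):
        inn = grp[grp["innervated"].astype(bool)]
        counts = {o: int((inn["orientation"] == o).sum()) for o in ORIENTATIONS}
        rows.append(
            {
                "terminal_id": tid,
                "terminal_type": grp["terminal_type"].iloc[0],
                "n_innervated": int(len(inn)),
                "percent_innervated": 100.0 * len(inn) / n_total_cells,
                "n_synapses": int(inn["n_synapses"].sum()),
                "selectivity_index": selectivity_index(counts),
            }
        )
    return pd.DataFrame(rows)
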