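"""End-to-end helper: cohorts/networks to a per-component metric table.

The long-format table produced here is the interchange object between the
extraction stage and everything downstream (group tests, size-distribution
fits, classification): one row per connected component, carrying subject
and network identity, size and link count, the raw metric battery, the
induced motif census, and the Z-score of each metric/motif against the
component's matched connected-random-graph null ensemble.

Null ensembles depend only on (n, l), so they are cached per (n, l) class
and seeded from ``(seed, n, l)`` — the table is reproducible regardless of
component order.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from mitotopo import metrics as _metrics
from mitotopo import motifs as _motifs
from mitotopo.cohort import SubjectRecord, SyntheticCohort
from mitotopo.metrics import METRIC_NAMES, extract_components
from mitotopo.motifs import MOTIF_CLASSES
from mitotopo.network import MitoNetwork
from mitotopo.nullmodel import NullCache, zscore

__all__ = ["component_metrics_table", "ZSCORED_COLUMNS"]

#: metric/motif columns that receive a null-model Z-score
ZSCORED_COLUMNS = tuple(
    m for m in METRIC_NAMES if m not in ("link_density",)
) + MOTIF_CLASSES


def component_metrics_table(
    source: SyntheticCohort | Iterable[MitoNetwork],
    null_cache: NullCache | None = None,
    n_random: int = 100,
    seed: int = 0,
    max_size: int | None = None,
    with_motifs: bool = True,
) -> pd.DataFrame:
    """One row per component: identity, raw metrics, motifs and Z-scores.

    Parameters
    ----------
    source
        A :class:`~mitotopo.cohort.SyntheticCohort` or an iterable of
        :class:`~mitotopo.network.MitoNetwork`.
    null_cache
        Shared :class:`~mitotopo.nullmodel.NullCache`; constructed from
        ``(n_random, seed)`` if not supplied.  Components of size 1 get no
        Z-scores (no null is defined).
    max_size
        Optional hard cap: components larger than this are still listed
        (size statistics) but skip metric/null computation.  ``None``
        computes everything.

    Returns
    -------
    pandas.DataFrame
        Columns: subject_id, group, side, network_id, component_id, size,
        links, updrs, the raw metrics, ``small_worldness``, motif counts,
        and a ``<name>_z`` column per Z-scored quantity (NaN = undefined).
    """
    if null_cache is None:
        null_cache = NullCache(
            n_random=n_random, seed=seed, count_motifs=with_motifs
        )
    if isinstance(source, SyntheticCohort):
        networks = [
            (net, rec) for rec in source.subjects for net in rec.networks
        ]
    else:
        networks = [(net, None) for net in source]
    rows: list[dict] = []
    for net, rec in networks:
        for ci, comp in enumerate(extract_components(net.graph)):
            rows.append(
                _component_row(
                    comp, net, rec, ci, null_cache, seed, max_size,
                    with_motifs,
                )
            )
    return pd.DataFrame(rows)


def _component_row(
    comp: nx.Graph,
    net: MitoNetwork,
    rec: SubjectRecord | None,
    ci: int,
    null_cache: NullCache,
    seed: int,
    max_size: int | None,
    with_motifs: bool,
) -> dict:
    n = comp.number_of_nodes()
    l = comp.number_of_edges()
    row: dict = {
        "subject_id": net.subject_id,
        "group": rec.group if rec is not None else None,
        "side": net.side,
        "network_id": net.network_id,
        "component_id": ci,
        "size": n,
        "links": l,
        "updrs": rec.updrs if rec is not None else None,
    }
    skip = n < 2 or (max_size is not None and n > max_size)
    if skip:
        for name in METRIC_NAMES + ("small_worldness",):
            row[name] = np.nan
        for cls in MOTIF_CLASSES:
            row[cls] = np.nan
        for name in ZSCORED_COLUMNS:
            row[f"{name}_z"] = np.nan
        return row
    mv = _metrics.compute_metrics(comp, seed=seed)
    ensemble = null_cache.get(n, l)
    mv.small_worldness = _metrics.small_worldness(comp, ensemble)
    row.update(
        {k: (np.nan if v is None else v) for k, v in mv.as_dict().items()
         if k not in ("size", "links")}
    )
    observed: dict[str, float | None] = {
        name: getattr(mv, name)
        for name in METRIC_NAMES
        if name != "link_density"
    }
    if with_motifs:
        counts = _motifs.count_motifs(comp)
        row.update(counts.as_dict())
        observed.update(
            (k, float(v)) for k, v in counts.as_dict().items()
        )
    else:
        for cls in MOTIF_CLASSES:
            row[cls] = np.nan
    for name in ZSCORED_COLUMNS:
        m = observed.get(name)
        if m is None or name not in ensemble.summaries:
            row[f"{name}_z"] = np.nan
            continue
        record = zscore(float(m), ensemble, name, component_id=ci)
        row[f"{name}_z"] = np.nan if record.undefined else record.z
    return row
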