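"""Geometric hydrogen-bond analysis on conformer ensembles.

A hydrogen bond is counted when the hydrogen-acceptor distance is below
0.25 nm and the donor-hydrogen-acceptor angle exceeds 135 degrees.
Donors are O-H and N-H groups with explicit hydrogens; acceptors are all
oxygens, with the two carboxylate oxygens pooled under the label
``O1A/B`` since they are chemically equivalent.  Occurrences can be
reweighted to the unbiased ensemble; only populations above a reporting
threshold (2% by default) are listed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ensemble import ConformerEnsemble
from .geometry import measure_angle


@dataclass(frozen=True)
class HBondCriterion:
    max_ha_distance: float = 0.25  # nm, hydrogen...acceptor
    min_dha_angle: float = 135.0   # degrees, donor-hydrogen-acceptor

    def __post_init__(self) -> None:
        if self.max_ha_distance <= 0:
            raise ValueError("distance cutoff must be positive")
        if not 0.0 < self.min_dha_angle <= 180.0:
            raise ValueError("angle cutoff must lie in (0, 180]")

    def satisfied(self, donor, hydrogen, acceptor) -> bool:
        d = float(np.linalg.norm(np.asarray(hydrogen) - np.asarray(acceptor)))
        if d >= self.max_ha_distance:
            return False
        return measure_angle(donor, hydrogen, acceptor) > self.min_dha_angle


def _acceptor_label(ens: ConformerEnsemble, idx: int) -> str:
    a = ens.atoms[idx]
    name = "O1A/B" if a.name in ("O1A", "O1B") else a.name
    return f"{a.residue_label}{name}"


def find_donors(ens: ConformerEnsemble) -> list[tuple[int, int]]:
    """(donor heavy atom, hydrogen) index pairs for O-H and N-H groups."""
    donors = []
    for h, atom in enumerate(ens.atoms):
        if atom.element != "H":
            continue
        for j in ens.neighbors(h):
            if ens.atoms[j].element in ("O", "N"):
                donors.append((j, h))
    return donors


def find_acceptors(ens: ConformerEnsemble) -> list[int]:
    return [i for i, a in enumerate(ens.atoms) if a.element == "O"]


def hbond_occurrence(ensemble: ConformerEnsemble,
                     criterion: HBondCriterion = HBondCriterion(),
                     weights=None, threshold: float = 2.0,
                     exclude_same_donor: bool = True) -> pd.DataFrame:
    """Weighted per-pair hydrogen-bond occurrence percentages.

    Pairs are labelled ``<res><H-name>-<res><acceptor>`` with O1A/O1B
    pooled.  The returned frame is filtered at ``threshold`` percent and
    sorted by occurrence; the ``error`` column is a binomial standard
    error on the weight-effective sample size (sum w)^2 / sum w^2.
    """
    donors = find_donors(ensemble)
    acceptors = find_acceptors(ensemble)
    if not donors or not acceptors:
        raise ValueError("no donors or no acceptors in topology")
    n = ensemble.n_frames
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,):
            raise ValueError("weights length must equal frame count")
    wsum = w.sum()
    ess = wsum ** 2 / np.sum(w ** 2)

    counts: dict[tuple[str, str], np.ndarray] = {}
    for d, h in donors:
        for a in acceptors:
            if a == d:
                continue
            if exclude_same_donor and a in ensemble.neighbors(h):
                continue
            dh = ensemble.atoms[d]
            key = (f"{ensemble.atoms[h].residue_label}{ensemble.atoms[h].name}",
                   _acceptor_label(ensemble, a))
            hits = counts.setdefault(key, np.zeros(n, dtype=bool))
            for f in range(n):
                if criterion.satisfied(ensemble.coords[f, d],
                                       ensemble.coords[f, h],
                                       ensemble.coords[f, a]):
                    hits[f] = True

    rows = []
    for (dl, al), hits in counts.items():
        occ = 100.0 * float(np.sum(w * hits) / wsum)
        p = occ / 100.0
        err = 100.0 * float(np.sqrt(max(p * (1 - p), 0.0) / ess))
        if occ > threshold:
            rows.append({"donor": dl, "acceptor": al,
                         "occurrence_percent": occ, "error_percent": err})
    df = pd.DataFrame(rows, columns=["donor", "acceptor",
                                     "occurrence_percent", "error_percent"])
    return df.sort_values("occurrence_percent", ascending=False,
                          ignore_index=True)
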