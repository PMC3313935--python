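"""Per-branch dN/dS and equilibrium-GC estimators, and evaluation statistics.

dN/dS per branch divides the mapped non-synonymous and synonymous counts by
the corresponding *neutral opportunities* of the mapping model: the expected
per-unit-time non-synonymous and synonymous fluxes of the same model with
its selection parameter set to 1.  With this normalization the estimator
equals the simulating omega in expectation when mapping and simulating
models coincide, and estimates are comparable across mapping models.  A raw
N/S ratio is available behind ``norm="raw_ratio"``.

Zero-count branches produce flagged, first-class special values rather than
exceptions: 0 synonymous substitutions with non-synonymous ones present give
``+inf`` (flag ``zero_ds``), 0 non-synonymous give 0 (flag ``zero_dn``), and
0/0 is reported as undefined (NaN) with both flags.

The equilibrium-GC approximation is ``theta* = AT→GC / (AT→GC + GC→AT)``;
branches with fewer than ``min_subs`` total mapped substitutions (10 by
default, compared as reals) are flagged as filtered because too few events
make the ratio unreliable.

Binned summaries use equal-count (quantile) classes with the median and the
median absolute deviation, MAD = median(|x - median(x)|), which resists the
outliers that dominate interval-based dispersion measures here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ParameterError
from .models import build_yn98

__all__ = [
    "BranchEstimate",
    "neutral_fluxes",
    "dnds_per_branch",
    "gc_star_per_branch",
    "relative_error",
    "mad",
    "summarize_bins",
    "ErrorSummary",
]


@dataclass
class BranchEstimate:
    """One per-branch statistic with flags and its supporting counts."""

    branch_id: int
    kind: str                      # "dnds" | "gc_star"
    value: float                   # may be +inf (dnds) or NaN (undefined)
    flags: tuple = ()
    counts: dict = field(default_factory=dict)

    @property
    def defined(self):
        return not math.isnan(self.value)

    @property
    def filtered(self):
        return "filtered_low_counts" in self.flags


def neutral_fluxes(model, register):
    """Expected per-unit-time flux of each register type under the model's
    neutral variant (selection parameter forced to 1).

    ``flux_s = sum_{(x,y) in s} pi_x q_xy`` of the neutral model.  Models
    without a selection parameter (e.g. the equal-rates model) are their own
    neutral variant.
    """
    if "omega" in model.params and model.params["omega"] != 1:
        if model.family != "yn98":
            raise ParameterError(f"no neutral variant defined for family {model.family!r}")
        neutral = build_yn98(model.params["kappa"], 1.0, codon_freqs=model.pi,
                             alphabet=model.alphabet)
    else:
        neutral = model
    fluxes = {}
    for s in register.types:
        fluxes[s] = float(np.sum(neutral.pi[:, None] * neutral.Q * register.masks[s]))
    return fluxes


def dnds_per_branch(counts, model, norm="neutral_flux"):
    """Per-branch dN/dS from a syn/nonsyn counts table.

    Parameters
    ----------
    counts : CountsTable
        Must carry ``syn`` and ``nonsyn`` types.
    model : SubstitutionModel
        The mapping model; its neutral fluxes provide the opportunity
        normalization.
    norm : {"neutral_flux", "raw_ratio"}
        ``raw_ratio`` skips the opportunity normalization and reports N/S.
    """
    if not {"syn", "nonsyn"} <= set(counts.types):
        raise ParameterError("counts table lacks syn/nonsyn types")
    if norm not in ("neutral_flux", "raw_ratio"):
        raise ParameterError(f"unknown normalization {norm!r}")
    if norm == "neutral_flux":
        from .models import register_dnds
        fluxes = neutral_fluxes(model, register_dnds(model.alphabet))
        e_n, e_s = fluxes["nonsyn"], fluxes["syn"]
    else:
        e_n = e_s = 1.0
    out = []
    for bid in counts.branch_ids:
        N = float(counts.per_branch.loc[bid, "nonsyn"])
        S = float(counts.per_branch.loc[bid, "syn"])
        dn, ds = N / e_n, S / e_s
        flags = []
        if N == 0:
            flags.append("zero_dn")
        if S == 0:
            flags.append("zero_ds")
        if S == 0 and N == 0:
            value = float("nan")
        elif S == 0:
            value = float("inf")
        elif N == 0:
            value = 0.0
        else:
            value = dn / ds
        out.append(BranchEstimate(branch_id=bid, kind="dnds", value=value,
                                  flags=tuple(flags),
                                  counts={"nonsyn": N, "syn": S}))
    return out


def gc_star_per_branch(counts, min_subs=10):
    """Equilibrium-GC approximation theta* = AT→GC / (AT→GC + GC→AT).

    Branches whose total mapped substitutions (all types) fall below
    ``min_subs`` are flagged ``filtered_low_counts``; their value is still
    reported when defined, so downstream code decides what to exclude.
    """
    if not {"AT->GC", "GC->AT"} <= set(counts.types):
        raise ParameterError("counts table lacks AT->GC/GC->AT types")
    totals = counts.totals()
    out = []
    for bid in counts.branch_ids:
        at2gc = float(counts.per_branch.loc[bid, "AT->GC"])
        gc2at = float(counts.per_branch.loc[bid, "GC->AT"])
        flags = []
        if float(totals.loc[bid]) < min_subs:
            flags.append("filtered_low_counts")
        if at2gc + gc2at == 0:
            value = float("nan")
            flags.append("undefined")
        else:
            value = at2gc / (at2gc + gc2at)
        out.append(BranchEstimate(branch_id=bid, kind="gc_star", value=value,
                                  flags=tuple(flags),
                                  counts={"AT->GC": at2gc, "GC->AT": gc2at,
                                          "total": float(totals.loc[bid])}))
    return out


def relative_error(estimate, truth, signed=False):
    """Relative estimation error |estimate - truth| / truth.

    ``truth`` must be > 0; an infinite estimate yields an infinite error.
    With ``signed=True`` the sign of (estimate - truth) is kept.
    """
    if not truth > 0:
        raise ParameterError(f"truth must be > 0, got {truth}")
    if math.isnan(estimate):
        return float("nan")
    if math.isinf(estimate):
        return float("inf")
    err = (estimate - truth) / truth
    return err if signed else abs(err)


def mad(values):
    """Median absolute deviation: median(|x - median(x)|)."""
    arr = np.asarray(values, dtype=float)
    med = np.median(arr)
    return float(np.median(np.abs(arr - med)))


@dataclass
class ErrorSummary:
    """Per-class medians and MADs from a quantile binning."""

    table: pd.DataFrame   # columns: class, key_median, median, mad, n

    def __iter__(self):
        return iter(self.table.itertuples(index=False))


def summarize_bins(values, bin_keys, n_classes):
    """Equal-count (quantile) binning of ``values`` ranked by ``bin_keys``.

    Returns one row per class with the class median, the median absolute
    deviation and the class size; class sizes differ by at most 1.
    """
    values = np.asarray(values, dtype=float)
    keys = np.asarray(bin_keys, dtype=float)
    if values.shape != keys.shape:
        raise ParameterError("values and bin_keys must align")
    if n_classes < 1:
        raise ParameterError("n_classes must be >= 1")
    if len(values) < n_classes:
        raise ParameterError(f"{len(values)} values cannot fill {n_classes} classes")
    order = np.argsort(keys, kind="stable")
    chunks = np.array_split(order, n_classes)
    rows = []
    for c, idx in enumerate(chunks):
        v = values[idx]
        rows.append({
            "class": c + 1,
            "key_median": float(np.median(keys[idx])),
            "median": float(np.median(v)),
            "mad": mad(v),
            "n": len(idx),
        })
    return ErrorSummary(table=pd.DataFrame(rows))
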