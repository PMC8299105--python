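"""Levins' niche-breadth index and generalist/specialist classification.

The niche breadth of OTU j is

    B_j = 1 / sum_i P_ij**2

where P_ij is the fraction of OTU j's total reads found in sample i (the
within-OTU normalization; see :mod:`microniche.io`). B ranges from 1 (all
reads in one sample) to N (reads spread evenly over N samples) and is
bounded above by the OTU's occurrence count.

Classification rules (fixed-threshold mode):

- *generalist*: mean within-sample relative abundance >= ``min_mean_relabund``
  (OTUs below the cut are "filtered"), global B strictly above
  ``generalist_b_threshold``, and occurrence strictly above
  ``generalist_occurrence_fraction`` of all samples.
- *habitat specialist*: within one region, B computed over that region's
  samples strictly below the region's threshold and in-region occurrence
  strictly above ``specialist_min_occurrence``. An OTU qualifying in two or
  more regions is not a specialist of any (the tie is recorded); a
  generalist call takes precedence over a specialist call.
- everything else is *medium* (or *filtered* when it fails the abundance cut
  and nothing else fires).

``auto_threshold`` mode replaces the fixed cuts by Tukey outlier fences of
the observed B distributions (upper fence globally, lower fence per region).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .io import OtuTable, SampleMetadata, otu_profiles, within_sample_relabund

#: Region-wise specialist B cuts for the three canonical bioclimatic regions.
DEFAULT_SPECIALIST_B_THRESHOLDS = {
    "subtropical": 12.0,
    "warm_temperate": 17.0,
    "temperate": 17.0,
}


def niche_breadth(profile) -> float:
    """Levins' B = 1 / sum(P**2) for one occupancy profile.

    ``profile`` must be non-negative and sum to 1 (within 1e-9). Equals k
    for a uniform profile over k samples and 1 for a point mass.
    """
    p = np.asarray(profile, dtype=float)
    if (p < 0).any():
        raise ValueError("profile entries must be >= 0")
    s = p.sum()
    if s == 0:
        raise ValueError("zero-sum profile")
    if abs(s - 1.0) > 1e-9:
        raise ValueError(f"profile must sum to 1 (got {s!r})")
    return float(1.0 / np.sum(p * p))


def suggest_outlier_threshold(b_values, tail: str = "upper") -> float:
    """Tukey fence of a B-value distribution (candidate classification cut).

    upper: Q3 + 1.5 IQR; lower: Q1 - 1.5 IQR, quartiles by linear
    interpolation.
    """
    v = np.asarray(list(b_values), dtype=float)
    if v.size < 4:
        raise ValueError("need at least 4 values to estimate outlier fences")
    q1, q3 = np.percentile(v, [25, 75], method="linear")
    iqr = q3 - q1
    if tail == "upper":
        return float(q3 + 1.5 * iqr)
    if tail == "lower":
        return float(q1 - 1.5 * iqr)
    raise ValueError("tail must be 'upper' or 'lower'")


class NicheBreadthClassifier(BaseEstimator):
    """Classify OTUs as generalist / habitat specialist / medium by B-value.

    Parameters
    ----------
    generalist_b_threshold : float, default 17
        Global B must strictly exceed this for a generalist call.
    generalist_occurrence_fraction : float, default 0.5
        Occurrence fraction must strictly exceed this for a generalist call.
    min_mean_relabund : float, default 2e-5
        OTUs with mean within-sample relative abundance strictly below this
        are excluded from generalist determination.
    specialist_b_thresholds : dict or float or None, default None
        Region -> B cut. None uses the canonical three-region defaults
        (12 / 17 / 17) where region names match, else raises.
        A scalar applies one cut to every region.
    specialist_min_occurrence : int, default 4
        In-region occurrence must strictly exceed this.
    auto_threshold : bool, default False
        Derive cuts from Tukey fences of the observed B distributions
        instead of the fixed values.

    Attributes
    ----------
    results_ : pandas.DataFrame
        Per-OTU B_global, per-region B, occurrence, mean relative abundance,
        label, and specialist tie report.
    labels_ : pandas.Series
        The label column of ``results_``.
    thresholds_ : dict
        The cuts actually applied (relevant in auto mode).
    """

    def __init__(
        self,
        generalist_b_threshold: float = 17.0,
        generalist_occurrence_fraction: float = 0.5,
        min_mean_relabund: float = 2e-5,
        specialist_b_thresholds=None,
        specialist_min_occurrence: int = 4,
        auto_threshold: bool = False,
    ):
        self.generalist_b_threshold = generalist_b_threshold
        self.generalist_occurrence_fraction = generalist_occurrence_fraction
        self.min_mean_relabund = min_mean_relabund
        self.specialist_b_thresholds = specialist_b_thresholds
        self.specialist_min_occurrence = specialist_min_occurrence
        self.auto_threshold = auto_threshold

    # -- helpers ----------------------------------------------------------

    def _region_threshold(self, region: str, b_region_values) -> float:
        if self.auto_threshold:
            vals = b_region_values[np.isfinite(b_region_values)]
            return max(suggest_outlier_threshold(vals, "lower"), 1.0)
        t = self.specialist_b_thresholds
        if t is None:
            if region in DEFAULT_SPECIALIST_B_THRESHOLDS:
                return DEFAULT_SPECIALIST_B_THRESHOLDS[region]
            raise ValueError(
                f"no specialist B threshold for region {region!r}; pass "
                "specialist_b_thresholds explicitly")
        if np.isscalar(t):
            return float(t)
        if region not in t:
            raise ValueError(f"no specialist B threshold for region {region!r}")
        return float(t[region])

    # -- estimator API ----------------------------------------------------

    def fit(self, table: OtuTable, metadata: SampleMetadata):
        """Compute B-values and labels for every OTU in ``table``."""
        missing = [s for s in table.sample_ids if s not in metadata.region]
        if missing:
            raise ValueError(f"samples missing region metadata: {missing[:5]}")
        regions = [metadata.region[s] for s in table.sample_ids]
        region_names = list(dict.fromkeys(regions))
        region_cols = {r: np.array([j for j, q in enumerate(regions) if q == r])
                       for r in region_names}
        for r, cols in region_cols.items():
            if cols.size < 2:
                raise ValueError(f"region {r!r} has fewer than 2 samples")

        counts = table.counts.astype(float)
        n_samples = table.n_samples
        occurrence = (counts > 0).sum(axis=1)
        occ_frac = occurrence / n_samples
        relabund = within_sample_relabund(table)
        mean_relabund = relabund.mean(axis=1)

        profiles = otu_profiles(table)
        with np.errstate(invalid="ignore", divide="ignore"):
            b_global = 1.0 / np.nansum(profiles**2, axis=1)
        b_global[occurrence == 0] = np.nan

        b_region = {}
        for r, cols in region_cols.items():
            sub = counts[:, cols]
            tot = sub.sum(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                pr = sub / tot[:, None]
                b = 1.0 / np.sum(pr * pr, axis=1)
            b[tot == 0] = np.nan
            b_region[r] = b

        if self.auto_threshold:
            passing = mean_relabund >= self.min_mean_relabund
            gen_b_cut = suggest_outlier_threshold(
                b_global[passing & np.isfinite(b_global)], "upper")
        else:
            gen_b_cut = float(self.generalist_b_threshold)
        spec_cuts = {r: self._region_threshold(r, b_region[r])
                     for r in region_names}

        labels = []
        ties = []
        for i in range(table.n_otus):
            passes_filter = mean_relabund[i] >= self.min_mean_relabund
            is_gen = (
                passes_filter
                and np.isfinite(b_global[i])
                and b_global[i] > gen_b_cut
                and occ_frac[i] > self.generalist_occurrence_fraction
            )
            if is_gen:
                labels.append("generalist")
                ties.append("")
                continue
            qual = []
            for r in region_names:
                occ_r = (counts[i, region_cols[r]] > 0).sum()
                b = b_region[r][i]
                if (occ_r > self.specialist_min_occurrence
                        and np.isfinite(b) and b < spec_cuts[r]):
                    qual.append(r)
            if len(qual) == 1:
                labels.append(f"specialist:{qual[0]}")
                ties.append("")
            else:
                ties.append(";".join(qual) if len(qual) > 1 else "")
                labels.append("medium" if passes_filter else "filtered")

        res = pd.DataFrame(
            {
                "B_global": b_global,
                **{f"B_{r}": b_region[r] for r in region_names},
                "occurrence_count": occurrence,
                "occurrence_fraction": occ_frac,
                "mean_relabund": mean_relabund,
                "label": labels,
                "specialist_tie_regions": ties,
            },
            index=pd.Index(table.otu_ids, name="otu_id"),
        )
        self.results_ = res
        self.labels_ = res["label"]
        self.thresholds_ = {"generalist_b": gen_b_cut, "specialist_b": spec_cuts}
        self.region_names_ = region_names
        return self

    def predict(self, table: OtuTable, metadata: SampleMetadata) -> pd.Series:
        """Fit on the given data and return the per-OTU labels."""
        return self.fit(table, metadata).labels_


def classify(table: OtuTable, metadata: SampleMetadata, config=None, **kwargs) -> pd.DataFrame:
    """Functional wrapper: classify every OTU and return the result table.

    ``config`` may be a pre-configured :class:`NicheBreadthClassifier`;
    keyword arguments override its parameters.
    """
    clf = config if isinstance(config, NicheBreadthClassifier) else NicheBreadthClassifier()
    if kwargs:
        clf = clf.set_params(**kwargs)
    return clf.fit(table, metadata).results_
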