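"""Regional z-score signatures, receptor-subunit switching, and the
four-modality cross-region concordance report.

Z-scores standardize each feature's donor-averaged regional abundance to
mean 0 / sample SD 1 across regions (computed independently per subclass
upstream). A receptor family is "switching" along an axis when at least
one of its subunit genes is classified positively correlated and another
negatively — the transcript-level signature of regionally remodeled
receptor composition. The concordance report compares region x region
correlation matrices from four modalities (spatial density, neighborhood
composition, expression, accessibility) through the correlation of their
upper triangles.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from cortaxis.io import ValidationError


@dataclass
class ZScoreMatrix:
    """Features x regions z-scores; constant rows are zeroed and flagged."""

    values: pd.DataFrame
    constant_features: list[str]
    source: str = "expression"
    subclass: str = ""
    sd_convention: str = "sample (n-1)"


def regional_zscore(region_means: pd.DataFrame, source: str = "expression",
                    subclass: str = "") -> ZScoreMatrix:
    """Standardize each feature row across regions.

    z = (value - row mean) / row sample SD (denominator n-1). Rows with
    zero variance become all zeros and are listed in
    ``constant_features``.
    """
    if region_means.shape[1] < 2:
        raise ValidationError("z-scores need >= 2 regions")
    values = region_means.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    # exact-range test: identical values can still give a tiny nonzero SD
    # through rounding of the mean
    constant = (np.ptp(values, axis=1) == 0) | (sd == 0).ravel()
    safe_sd = np.where(constant[:, None], 1.0, sd)
    z = (values - mean) / safe_sd
    z[constant] = 0.0
    return ZScoreMatrix(
        values=pd.DataFrame(z, index=region_means.index,
                            columns=region_means.columns),
        constant_features=[f for f, c in zip(region_means.index, constant) if c],
        source=source,
        subclass=subclass,
    )


def detect_subunit_switching(
    families: dict[str, list[str]], gene_classes: pd.DataFrame
) -> pd.DataFrame:
    """Per-family switching report from a classified axis screen.

    A family switches when it has at least one positive-class and one
    negative-class subunit. Families with no subunit in the screen are
    reported as unevaluable. ``n_changed`` counts non-null subunits.
    """
    seen: dict[str, str] = {}
    for fam, genes in families.items():
        for g in genes:
            if g in seen and seen[g] != fam:
                raise ValidationError(
                    f"gene {g!r} appears in families {seen[g]!r} and {fam!r}"
                )
            seen[g] = fam
    cls = gene_classes.set_index("feature")
    rows = []
    for fam, genes in families.items():
        present = [g for g in genes if g in cls.index]
        detail = {
            g: {"sign_class": str(cls.loc[g, "sign_class"]),
                "r": float(cls.loc[g, "r"])}
            for g in present
        }
        signs = {d["sign_class"] for d in detail.values()}
        rows.append(
            {
                "family": fam,
                "evaluable": bool(present),
                "switching": "positive" in signs and "negative" in signs,
                "n_subunits": len(genes),
                "n_evaluated": len(present),
                "n_changed": sum(
                    1 for d in detail.values() if d["sign_class"] != "null"
                ),
                "subunits": detail,
            }
        )
    return pd.DataFrame(rows)


def molecular_region_correlation(
    abundance: pd.DataFrame, sample_regions: list[str]
) -> pd.DataFrame:
    """Region x region Pearson correlation of donor-averaged abundance.

    ``abundance`` is features x samples (post-filtering background);
    samples are first averaged within region.
    """
    regions = sorted(set(sample_regions))
    if len(regions) < 2:
        raise ValidationError("need >= 2 regions")
    labels = np.asarray(sample_regions)
    values = abundance.to_numpy(dtype=float)
    means = {r: values[:, labels == r].mean(axis=1) for r in regions}
    mat = np.ones((len(regions), len(regions)))
    for i, j in combinations(range(len(regions)), 2):
        mat[i, j] = mat[j, i] = float(
            np.corrcoef(means[regions[i]], means[regions[j]])[0, 1]
        )
    return pd.DataFrame(mat, index=regions, columns=regions)


def modality_agreement_index(a: pd.DataFrame, b: pd.DataFrame) -> float:
    """Pearson correlation of the upper triangles of two region x region
    correlation matrices (symmetric in its arguments)."""
    if list(a.index) != list(b.index):
        raise ValidationError("matrices must share the same region set/order")
    iu = np.triu_indices(len(a), k=1)
    x = a.to_numpy()[iu]
    y = b.to_numpy()[iu]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def assemble_modality_concordance(
    density_corr: pd.DataFrame,
    neighbor_corr: pd.DataFrame,
    expr_corr: pd.DataFrame,
    atac_corr: pd.DataFrame,
    subclass: str = "",
) -> dict:
    """Bundle the four modality matrices with pairwise agreement indices.

    Matrices are restricted to their common region set (reported). With
    fewer than 3 common regions the upper triangle is too short to
    correlate and agreement indices are skipped.
    """
    named = {
        "density": density_corr,
        "neighborhood": neighbor_corr,
        "expression": expr_corr,
        "accessibility": atac_corr,
    }
    common = sorted(
        set.intersection(*(set(m.index) for m in named.values()))
    )
    restricted = {k: m.loc[common, common] for k, m in named.items()}
    report: dict = {
        "subclass": subclass,
        "regions": common,
        "matrices": {k: m.to_dict() for k, m in restricted.items()},
        "agreement": {},
    }
    if len(common) < 3:
        report["agreement_skipped"] = f"only {len(common)} common regions"
        return report
    for ka, kb in combinations(named, 2):
        report["agreement"][f"{ka}~{kb}"] = modality_agreement_index(
            restricted[ka], restricted[kb]
        )
    return report
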