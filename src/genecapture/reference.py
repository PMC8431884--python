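"""Published diversity-index tables for three wild banana (Musa) species.

These are the printed regional and per-locality index values from the field
survey of *M. acuminata* subsp. *banksii*, *M. balbisiana* and *M. maclayi*
populations and their seed collections (the raw genotypes behind them are
not publicly deposited).  They serve as worked-example inputs: capture
proportions recomputed from these tables are the package's reference
figures for how completely seed collections represent their source
populations.
"""

from __future__ import annotations

import pandas as pd

from .diversity import capture_proportion

__all__ = [
    "regional_indices",
    "local_indices",
    "regional_capture_percentages",
    "local_capture_statistics",
]

SPECIES = ("M. acuminata", "M. balbisiana", "M. maclayi")

# Regional level: samples pooled across the five local populations (or the
# five maternal bunches) per species.
_REGIONAL_ROWS = [
    # species, sample, N, AR, PA, MLG, Hprime, lambda, E5, Hexp, Ho
    ("M. acuminata", "population", 76, 73, 33, 70, 4.214, 0.984, 0.948, 0.290, 0.045),
    ("M. acuminata", "seeds", 104, 37, 2, 25, 2.704, 0.905, 0.684, 0.238, 0.023),
    ("M. balbisiana", "population", 83, 48, 16, 82, 4.402, 0.988, 0.993, 0.314, 0.336),
    ("M. balbisiana", "seeds", 73, 39, 6, 60, 4.029, 0.981, 0.919, 0.227, 0.083),
    ("M. maclayi", "population", 57, 242, 27, 55, 3.994, 0.981, 0.981, 0.897, 0.723),
    ("M. maclayi", "seeds", 52, 224, 8, 52, 3.951, 0.981, 1.000, 0.872, 0.750),
]

# Local level: each local population, and the one seed bunch collected from
# it, kept separate.
_LOCAL_ROWS = [
    # species, locality, sample, AR, Ho, Hexp, Fis
    ("M. acuminata", "Shungol", "population", 35, 0.033, 0.225, 0.880),
    ("M. acuminata", "Nuru", "population", 50, 0.102, 0.359, 0.720),
    ("M. acuminata", "Ramu", "population", 48, 0.076, 0.268, 0.417),
    ("M. acuminata", "Sandaun", "population", 25, 0.014, 0.056, 0.603),
    ("M. acuminata", "Vanimo", "population", 40, 0.008, 0.267, 0.976),
    ("M. acuminata", "Shungol", "seeds", 22, 0.037, 0.047, 0.098),
    ("M. acuminata", "Nuru", "seeds", 19, 0.000, 0.000, 0.000),
    ("M. acuminata", "Ramu", "seeds", 21, 0.053, 0.053, -0.009),
    ("M. acuminata", "Sandaun", "seeds", 22, 0.007, 0.007, 0.000),
    ("M. acuminata", "Vanimo", "seeds", 19, 0.000, 0.000, 0.000),
    ("M. balbisiana", "Can Cau", "population", 20, 0.298, 0.228, -0.318),
    ("M. balbisiana", "Khe Ngau", "population", 32, 0.389, 0.356, 0.068),
    ("M. balbisiana", "Muong Cau", "population", 22, 0.252, 0.209, -0.116),
    ("M. balbisiana", "Na Bo", "population", 23, 0.312, 0.253, -0.195),
    ("M. balbisiana", "Seo Leng", "population", 27, 0.392, 0.332, -0.189),
    ("M. balbisiana", "Can Cau", "seeds", 30, 0.183, 0.230, 0.118),
    ("M. balbisiana", "Khe Ngau", "seeds", 15, 0.075, 0.118, 0.216),
    ("M. balbisiana", "Muong Cau", "seeds", 15, 0.102, 0.116, 0.193),
    ("M. balbisiana", "Na Bo", "seeds", 14, 0.021, 0.053, 0.462),
    ("M. balbisiana", "Seo Leng", "seeds", 15, 0.070, 0.072, 0.155),
    ("M. maclayi", "Aropa", "population", 117, 0.725, 0.862, 0.161),
    ("M. maclayi", "Boku", "population", 92, 0.673, 0.753, 0.090),
    ("M. maclayi", "Kangu", "population", 113, 0.737, 0.847, 0.133),
    ("M. maclayi", "Kurai", "population", 105, 0.705, 0.817, 0.136),
    ("M. maclayi", "Panguna", "population", 112, 0.737, 0.805, 0.089),
    ("M. maclayi", "Aropa", "seeds", 86, 0.793, 0.741, -0.073),
    ("M. maclayi", "Boku", "seeds", 91, 0.722, 0.680, -0.046),
    ("M. maclayi", "Kangu", "seeds", 109, 0.737, 0.698, -0.066),
    ("M. maclayi", "Kurai", "seeds", 64, 0.829, 0.746, -0.113),
    ("M. maclayi", "Panguna", "seeds", 69, 0.699, 0.665, -0.058),
]


def regional_indices() -> pd.DataFrame:
    """Regional (pooled) diversity indices per species and sample type."""
    return pd.DataFrame(
        _REGIONAL_ROWS,
        columns=["species", "sample", "N", "AR", "PA", "MLG",
                 "Hprime", "lambda", "E5", "Hexp", "Ho"],
    )


def local_indices() -> pd.DataFrame:
    """Per-locality diversity indices per species and sample type."""
    return pd.DataFrame(
        _LOCAL_ROWS,
        columns=["species", "locality", "sample", "AR", "Ho", "Hexp", "Fis"],
    )


def regional_capture_percentages() -> dict[str, float]:
    """Regional genetic capture: pooled seed AR as a percent of pooled
    population AR, per species."""
    df = regional_indices().set_index(["species", "sample"])
    return {
        sp: capture_proportion(
            df.loc[(sp, "seeds"), "AR"], df.loc[(sp, "population"), "AR"]
        )
        for sp in SPECIES
    }


def local_capture_statistics() -> pd.DataFrame:
    """Mean and SD (n-1 denominator) of per-locality seed/population AR
    capture percentages, per species."""
    df = local_indices()
    wide = df.pivot_table(
        index=["species", "locality"], columns="sample", values="AR"
    )
    pct = 100.0 * wide["seeds"] / wide["population"]
    out = pct.groupby(level="species").agg(["mean", "std", "count"])
    return out.rename(columns={"count": "n_localities"})
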