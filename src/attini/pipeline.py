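"""End-to-end orchestration of the analysis stages on a study directory or
an in-memory synthetic study."""

from __future__ import annotations

import pandas as pd

from . import comparative, geoclim, traits

DEFAULT_TRANSFORMS = {
    "worker_size_variation": "sqrt",
    "queen_worker_dimorphism": "ln",
    "colony_size": "ln",
}


def prepare_study_data(study, cellsize_arcmin: float | None = None) -> pd.DataFrame:
    """Aggregate a synthetic study's observations, extract its climate
    covariates and apply the standard transformations.

    Returns a species table ready for :func:`attini.comparative.
    run_averaged_analysis`: transformed social traits plus environmental
    means and mean latitude.
    """
    table, _prov = traits.aggregate_observations(study.observations)
    cs = cellsize_arcmin or study.config.cellsize_arcmin
    coarse = [geoclim.resample_grid(g, cs) for g in study.grids]
    kept, _log = geoclim.filter_localities(study.localities)
    env = geoclim.species_environment_means(kept, coarse)
    table = table.join(env, how="left")
    transforms = {k: v for k, v in DEFAULT_TRANSFORMS.items()
                  if k in table.columns}
    table, _tprov = traits.transform_table(table, transforms, on_error="drop")
    return table


def analyse_study(study, response: str = "worker_size_variation_sqrt",
                  candidates=("colony_size_ln",) + geoclim.CLIMATE_VARIABLES,
                  tree=None, **kwargs) -> dict:
    """Run the full averaged-model analysis for one response of a study.

    Defaults to the non-reproductive division-of-labour model set:
    square-root worker size variation against ln colony size and the four
    climate covariates.  ``tree`` defaults to the study's true chronogram.
    Extra keyword arguments pass through to
    :func:`attini.comparative.run_averaged_analysis`.
    """
    data = prepare_study_data(study)
    tree = tree if tree is not None else study.tree
    candidates = [c for c in candidates if c in data.columns]
    return comparative.run_averaged_analysis(
        data, tree, response, candidates, **kwargs)
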