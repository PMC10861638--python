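"""Confirmatory variable-set presets for the two published discriminant models.

The elevation model leans on elevation-related behaviours (elevation gain,
farm-centred 85th elevation quantile, relative mean elevation, 15th slope
quantile); the exploration model swaps those for exploration behaviours
(horizontal and adjusted horizontal distance, home range, maximum slope).
Both share seven variables.  Eleven variables each, union fifteen.
"""

ELEVATION_MODEL = [
    "slope_mean",
    "rel_ele_mean",
    "rel_ele_mean_cv",
    "ele_range",
    "ele_gain",
    "rel_ele_range_cv",
    "ele85_farm_cv",
    "slope15",
    "sp_tortuosity",
    "ele85_farm",
    "slope_mean_cv",
]

EXPLORATION_MODEL = [
    "dist_ho",
    "slope_mean",
    "slope_max",
    "sp_tortuosity",
    "rel_ele_mean_cv",
    "hr_mcp",
    "adj_dist_ho",
    "rel_ele_range_cv",
    "ele85_farm_cv",
    "ele_range",
    "slope_mean_cv",
]

SHARED_VARIABLES = sorted(set(ELEVATION_MODEL) & set(EXPLORATION_MODEL))


def preset_variable_sets() -> dict[str, list[str]]:
    """Named confirmatory variable lists (copies; callers may mutate)."""
    return {
        "elevation": list(ELEVATION_MODEL),
        "exploration": list(EXPLORATION_MODEL),
    }
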