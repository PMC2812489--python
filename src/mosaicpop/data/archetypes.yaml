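# Default life-history archetype parameterizations, version 1.
#
# Four contrasting archetypes: a ground beetle (fast-reproducing, short
# dispersing, flightless, needs overwintering habitat near its summer
# fields), a field vole (slower-reproducing, short-dispersing grassland
# specialist with elevated matrix mortality), a skylark (slow-reproducing
# far-dispersing open-field breeder that avoids nesting near trees) and a
# linyphiid spider (fast-reproducing ballooner with high dispersal
# mortality).  Rates are per-capita per year; distances in cells;
# probabilities in [0, 1].  Only ordinal relations between archetypes
# (who disperses farther, who reproduces faster) are load-bearing; the
# absolute values are this package's desk-scale defaults.
config_version: 1
archetypes:
  beetle:
    r_max: 6.0
    semelparous: true
    d_max: 4
    dispersal_mortality: 0.10
    barriers_block: true
    complementation_radius: 3
    complementation_types: [field_boundary, hedgerow]
    avoidance_radius: 0
    avoidance_types: []
    fecundity_multiplier:
      rotational_field: 1.0
      field_boundary: 0.6
      hedgerow: 0.5
      roadside_verge: 0.5
      grassland: 0.3
      forest: 0.0
    overwinter_survival:
      rotational_field: 0.5
      field_boundary: 0.6
      hedgerow: 0.6
      roadside_verge: 0.5
      grassland: 0.4
      forest: 0.1
    capacity_density:
      rotational_field: 2.0
      field_boundary: 2.0
      hedgerow: 2.0
      roadside_verge: 1.5
      grassland: 1.0
      forest: 0.0
  vole:
    r_max: 3.0
    semelparous: false
    d_max: 4
    dispersal_mortality: 0.15
    barriers_block: true
    complementation_radius: 0
    complementation_types: []
    avoidance_radius: 0
    avoidance_types: []
    fecundity_multiplier:
      grassland: 1.0
      roadside_verge: 0.6
      field_boundary: 0.5
      hedgerow: 0.4
      rotational_field: 0.15
      forest: 0.1
    overwinter_survival:
      grassland: 0.65
      roadside_verge: 0.5
      field_boundary: 0.5
      hedgerow: 0.5
      rotational_field: 0.2
      forest: 0.3
    capacity_density:
      grassland: 3.0
      roadside_verge: 1.5
      field_boundary: 1.5
      hedgerow: 1.0
      rotational_field: 0.3
      forest: 0.2
  skylark:
    r_max: 2.0
    semelparous: false
    d_max: 40
    dispersal_mortality: 0.05
    barriers_block: false
    complementation_radius: 0
    complementation_types: []
    avoidance_radius: 2
    avoidance_types: [forest, hedgerow]
    fecundity_multiplier:
      rotational_field: 1.0
      grassland: 0.7
      roadside_verge: 0.6
      field_boundary: 0.5
      hedgerow: 0.0
      forest: 0.0
    overwinter_survival:
      rotational_field: 0.7
      grassland: 0.7
      roadside_verge: 0.7
      field_boundary: 0.7
      hedgerow: 0.3
      forest: 0.2
    capacity_density:
      rotational_field: 0.8
      grassland: 0.6
      roadside_verge: 0.5
      field_boundary: 0.4
      hedgerow: 0.1
      forest: 0.0
  spider:
    r_max: 8.0
    semelparous: true
    # ballooning is landscape-scale dispersal: the settlement distribution is
    # near-uniform over the mosaic, so arrangement does not matter but
    # composition does
    d_max: 150
    dispersal_mortality: 0.5
    barriers_block: false
    complementation_radius: 0
    complementation_types: []
    avoidance_radius: 0
    avoidance_types: []
    fecundity_multiplier:
      rotational_field: 1.0
      grassland: 0.8
      roadside_verge: 0.8
      field_boundary: 0.7
      hedgerow: 0.5
      forest: 0.2
    overwinter_survival:
      rotational_field: 0.5
      grassland: 0.5
      roadside_verge: 0.5
      field_boundary: 0.5
      hedgerow: 0.5
      forest: 0.3
    capacity_density:
      rotational_field: 3.0
      grassland: 2.0
      roadside_verge: 2.0
      field_boundary: 2.0
      hedgerow: 1.0
      forest: 0.5
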