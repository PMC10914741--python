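issue_token,impact,score
ZERO_COORDINATE,exclude,-9
COORDINATE_OUT_OF_RANGE,exclude,-9
COORDINATE_INVALID,exclude,-9
COUNTRY_COORDINATE_MISMATCH,exclude,-9
COORDINATE_REPROJECTION_FAILED,exclude,-9
PRESUMED_SWAPPED_COORDINATE,medium,-3
PRESUMED_NEGATED_LONGITUDE,medium,-3
PRESUMED_NEGATED_LATITUDE,medium,-3
COORDINATE_REPROJECTED,medium,-3
COORDINATE_REPROJECTION_SUSPICIOUS,medium,-3
GEODETIC_DATUM_INVALID,medium,-3
COORDINATE_UNCERTAINTY_METERS_INVALID,medium,-3
COORDINATE_PRECISION_INVALID,medium,-3
COORDINATE_ACCURACY_INVALID,medium,-3
COORDINATE_PRECISION_UNCERTAINTY_MISMATCH,medium,-3
FOOTPRINT_SRS_INVALID,medium,-3
FOOTPRINT_WKT_INVALID,medium,-3
COUNTRY_MISMATCH,medium,-3
CONTINENT_COORDINATE_MISMATCH,medium,-3
COORDINATE_ROUNDED,low,-1
GEODETIC_DATUM_ASSUMED_WGS84,low,-1
FOOTPRINT_WKT_MISMATCH,low,-1
CONTINENT_COUNTRY_MISMATCH,low,-1
CONTINENT_INVALID,low,-1
GEOREFERENCED_DATE_UNLIKELY,low,-1
GEOREFERENCED_DATE_INVALID,low,-1
ELEVATION_UNLIKELY,low,-1
ELEVATION_MIN_MAX_SWAPPED,low,-1
ELEVATION_NOT_METRIC,low,-1
ELEVATION_NON_NUMERIC,low,-1
COUNTRY_INVALID,none,0
COUNTRY_DERIVED_FROM_COORDINATES,none,0
CONTINENT_DERIVED_FROM_COORDINATES,none,0
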