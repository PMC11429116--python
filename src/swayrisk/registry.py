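"""Feature registry: the 40 Prieto CoP indices and 7 descriptive variables.

Index names use stable snake_case; resultant-distance (RD) variants carry no
suffix, matching the convention in the stabilometry literature where e.g.
"Mean distance" denotes the RD quantity and "Mean distance-AP" its
antero-posterior counterpart. ``PRINTED_NAMES`` maps each snake_case name to
the display form used in reports.
"""

from __future__ import annotations

# --- time-domain and hybrid indices (25) -----------------------------------
TIME_DOMAIN_INDICES: tuple[str, ...] = (
    "mean_dist", "mean_dist_ap", "mean_dist_ml",
    "rms_dist", "rms_dist_ap", "rms_dist_ml",
    "std_rd", "std_ap", "std_ml",
    "range", "range_ap", "range_ml",
    "total_length", "total_length_ap", "total_length_ml",
    "mean_velocity", "mean_velocity_ap", "mean_velocity_ml",
    "covariance_ml",
    "ellipse_area_95", "circle_area_95", "sway_area",
    "mean_freq", "mean_freq_ap", "mean_freq_ml",
)

# --- frequency-domain indices, per direction RD/AP/ML (15) ------------------
SPECTRAL_INDICES: tuple[str, ...] = (
    "total_power", "total_power_ap", "total_power_ml",
    "power_freq_50", "power_freq_50_ap", "power_freq_50_ml",
    "power_freq_95", "power_freq_95_ap", "power_freq_95_ml",
    "centroid_freq", "centroid_freq_ap", "centroid_freq_ml",
    "freq_dispersion", "freq_dispersion_ap", "freq_dispersion_ml",
)

COP_INDICES: tuple[str, ...] = TIME_DOMAIN_INDICES + SPECTRAL_INDICES
assert len(COP_INDICES) == 40

#: Subject descriptive variables used as predictors (sex encoded 1=woman, 0=man).
DESCRIPTIVE_FEATURES: tuple[str, ...] = (
    "sex", "age", "height", "weight", "bmi", "foot_length", "polypharmacy",
)

#: All m = 47 selectable features, CoP indices first.
ALL_FEATURES: tuple[str, ...] = COP_INDICES + DESCRIPTIVE_FEATURES

#: Metadata columns allowed in a feature table besides the features.
META_COLUMNS: tuple[str, ...] = ("subject_id", "trial_index", "label")

LABEL_FALL_RISK = "Fall Risk"
LABEL_NON_FALL_RISK = "Non-Fall Risk"

#: The 11-feature initial solution for the selection sweep: 4 descriptive
#: variables plus 7 CoP indices with prior evidence of fall-risk association.
SEED_FEATURES: tuple[str, ...] = (
    "sex", "bmi", "age", "polypharmacy",
    "total_length_ml", "total_length_ap", "ellipse_area_95",
    "mean_velocity", "mean_velocity_ap", "mean_freq", "rms_dist",
)

PRINTED_NAMES: dict[str, str] = {
    "mean_dist": "Mean distance",
    "mean_dist_ap": "Mean distance-AP",
    "mean_dist_ml": "Mean distance-ML",
    "rms_dist": "RMS distance",
    "rms_dist_ap": "RMS distance-AP",
    "rms_dist_ml": "RMS distance-ML",
    "std_rd": "Standard deviation of RD",
    "std_ap": "Standard deviation-AP",
    "std_ml": "Standard deviation-ML",
    "range": "Range",
    "range_ap": "Range-AP",
    "range_ml": "Range-ML",
    "total_length": "Total length",
    "total_length_ap": "Total length AP",
    "total_length_ml": "Total length ML",
    "mean_velocity": "Mean velocity",
    "mean_velocity_ap": "Mean velocity-AP",
    "mean_velocity_ml": "Mean velocity-ML",
    "covariance_ml": "Covariance-ML",
    "ellipse_area_95": "95% conf. ellipse area",
    "circle_area_95": "95% conf. circle area",
    "sway_area": "Sway area",
    "mean_freq": "Mean frequency",
    "mean_freq_ap": "Mean frequency-AP",
    "mean_freq_ml": "Mean frequency-ML",
    "total_power": "Total power-RD",
    "total_power_ap": "Total power-AP",
    "total_power_ml": "Total power-ML",
    "power_freq_50": "50% power frequency-RD",
    "power_freq_50_ap": "50% power frequency-AP",
    "power_freq_50_ml": "50% power frequency-ML",
    "power_freq_95": "95% power frequency-RD",
    "power_freq_95_ap": "95% power frequency-AP",
    "power_freq_95_ml": "95% power frequency-ML",
    "centroid_freq": "Centroidal frequency-RD",
    "centroid_freq_ap": "Centroidal frequency-AP",
    "centroid_freq_ml": "Centroidal frequency-ML",
    "freq_dispersion": "Frequency dispersion-RD",
    "freq_dispersion_ap": "Frequency dispersion-AP",
    "freq_dispersion_ml": "Frequency dispersion-ML",
    "sex": "Sex",
    "age": "Age",
    "height": "Height",
    "weight": "Weight",
    "bmi": "BMI",
    "foot_length": "Foot length",
    "polypharmacy": "Polypharmacy",
}
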