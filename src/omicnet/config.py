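"""Fixed numerical conventions and registries.

Everything here is a package-level constant so that analyses are
reproducible and the conventions can be inspected (and, where a function
exposes the corresponding keyword, overridden per call).
"""

# --- Zi-Pi role classification (Guimera-Amaral convention) ---------------
ZI_THRESHOLD = 2.5
PI_THRESHOLD = 0.62

# --- RMT threshold scan ---------------------------------------------------
RMT_T_MIN = 0.3
RMT_T_MAX = 0.9
RMT_T_STEP = 0.01
RMT_N_BINS = 20          # NNSD histogram bins
RMT_S_MAX = 3.0          # NNSD histogram support [0, s_max]
RMT_CONSECUTIVE = 2      # grid points that must favour Poisson before a call
RMT_MIN_EIGEN = 20       # usable eigenvalues required at a threshold
RMT_DEGENERACY_TOL = 1e-8
RMT_UNFOLD_TRIM = 0.05   # spectrum fraction trimmed per edge before unfolding
RMT_SPLINE_SMOOTH = 0.01  # smoothing s of the unfolding spline fit to the ECDF

# --- layout conventions ---------------------------------------------------
ANGLE_START_DEG = 90.0   # first node / first vertex at 12 o'clock
POLYCIRCLE_RADIUS = 0.3  # per-group circle radius in as_polycircle
CIRCLEPACK_INNER_SCALE = 0.8

# --- topology report ------------------------------------------------------
#: Versioned registry of the headline global metrics.  Fourteen global
#: network metrics plus three per-node centrality summaries = 17.
TOPOLOGY_METRICS_VERSION = "1.0"
TOPOLOGY_METRICS = (
    "n_nodes",
    "n_edges",
    "edge_density",
    "proportion_negative_edges",
    "average_degree",
    "average_path_length",
    "diameter",
    "average_clustering",
    "transitivity",
    "global_efficiency",
    "modularity",
    "natural_connectivity",
    "n_components",
    "largest_component_fraction",
    "mean_betweenness",
    "mean_closeness",
    "mean_eigenvector",
)
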