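{
  "patterns": [
    {
      "n_ascans_per_bscan": 24,
      "n_positions": 8,
      "repeats": 3,
      "interscan_time_ms": 1.5,
      "fov_mm": [
        0.288,
        0.096
      ],
      "name": "256"
    },
    {
      "n_ascans_per_bscan": 24,
      "n_positions": 8,
      "repeats": 3,
      "interscan_time_ms": 3.0,
      "fov_mm": [
        0.288,
        0.096
      ],
      "name": "512"
    },
    {
      "n_ascans_per_bscan": 24,
      "n_positions": 8,
      "repeats": 3,
      "interscan_time_ms": 5.8,
      "fov_mm": [
        0.288,
        0.096
      ],
      "name": "1024"
    }
  ],
  "phantom": {
    "grid": [
      42,
      24,
      8
    ],
    "axial_pitch_um": 12.0,
    "surface": {
      "type": "dome",
      "z0": 12.0,
      "gx": 0.0,
      "gy": 0.0,
      "amplitude": 4.0,
      "sigma_frac": 0.5
    },
    "vessel_layers": [
      {
        "name": "superficial",
        "depth_range_um": [
          50.0,
          70.0
        ],
        "disks": [
          {
            "center": [
              6.0,
              2.0
            ],
            "radius_px": 2.6
          },
          {
            "center": [
              12.0,
              5.0
            ],
            "radius_px": 2.6
          },
          {
            "center": [
              18.0,
              2.0
            ],
            "radius_px": 2.6
          }
        ],
        "flow_speed_um_ms": 0.55
      },
      {
        "name": "deep",
        "depth_range_um": [
          320.0,
          340.0
        ],
        "disks": [
          {
            "center": [
              10.0,
              4.0
            ],
            "radius_px": 2.6
          },
          {
            "center": [
              14.0,
              3.0
            ],
            "radius_px": 2.6
          }
        ],
        "flow_speed_um_ms": 0.9
      }
    ],
    "static_tissue_amplitude": 1.0,
    "speckle": {
      "resolution_radius_um": 4.0,
      "noise_floor_sigma": 0.02,
      "correlation_law": "gaussian"
    },
    "seed": 1
  },
  "cohort": {
    "groups": [
      {
        "name": "g1",
        "n_subjects": 2,
        "schedule": {
          "baseline": 1.0,
          "ischemia": 0.0,
          "45": 1.0,
          "60": 1.0
        }
      },
      {
        "name": "g2",
        "n_subjects": 2,
        "schedule": {
          "baseline": 1.0,
          "ischemia": 0.0,
          "45": 1.0,
          "60": 1.0
        }
      }
    ],
    "time_points": [
      "baseline",
      "ischemia",
      "45",
      "60"
    ],
    "between_subject_cv": 0.1,
    "outcome_model": {
      "intercept": 0.0,
      "slope": 1.0,
      "noise_sd": 0.0,
      "layer": "superficial"
    },
    "seed": 1
  },
  "layers": [
    {
      "name": "superficial",
      "depth_range_um": [
        50.0,
        70.0
      ],
      "contributing_patterns": [
        "256",
        "512",
        "1024"
      ]
    },
    {
      "name": "deep",
      "depth_range_um": [
        320.0,
        340.0
      ],
      "contributing_patterns": [
        "256",
        "512"
      ]
    }
  ],
  "processing": {
    "mask_threshold": "auto",
    "mask_k": 3.0,
    "noise_rows": 8,
    "surface_threshold_k": 4.0,
    "surface_axial_median": 3,
    "surface_median": 3,
    "fusion_grid": null
  },
  "roi": {
    "center": null,
    "radius_px": null,
    "radius_frac": 0.4
  },
  "stats": {
    "alpha": 0.05,
    "correction": null,
    "baseline_label": "baseline"
  },
  "seed": 1,
  "output_dir": "octaflow_out"
}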