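{
  "boxes": [
    {
      "omega_box": [
        [
          0.0,
          500.0
        ],
        [
          0.0,
          1000.0
        ]
      ],
      "s_interval": [
        0.1,
        40.0
      ]
    },
    {
      "omega_box": [
        [
          0.0,
          500.0
        ],
        [
          0.0,
          1000.0
        ]
      ],
      "s_interval": [
        2.0,
        300.0
      ]
    }
  ],
  "extra_conditions": [],
  "multistart": 2000,
  "n_folds": 4,
  "n_genes": 2,
  "objectives": [
    "psi"
  ],
  "s_window": [
    0.1,
    330.0
  ],
  "schema_version": 1,
  "seed": 0,
  "signal_mask": [
    true,
    true
  ],
  "target_labels": [
    "mushroom",
    "inverted_mushroom"
  ],
  "tying": [
    [
      "leak[1]",
      "leak[0]"
    ],
    [
      "degradation[0]",
      1.0
    ]
  ],
  "x_bounds": [
    [
      10.0,
      2000.0
    ],
    [
      1.0,
      500.0
    ],
    [
      10.0,
      2000.0
    ],
    [
      0.001,
      1.0
    ],
    [
      50.0,
      500.0
    ],
    [
      50.0,
      500.0
    ],
    [
      0.1,
      10.0
    ],
    [
      1.0,
      300.0
    ],
    [
      1.0,
      300.0
    ]
  ],
  "x_names": [
    "p0",
    "p1",
    "p2",
    "k",
    "R1",
    "R2",
    "dv",
    "K1",
    "K2"
  ],
  "y_lower": [
    [
      -1,
      -1
    ],
    [
      -1,
      -1
    ]
  ],
  "y_upper": [
    [
      1,
      1
    ],
    [
      1,
      1
    ]
  ]
}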