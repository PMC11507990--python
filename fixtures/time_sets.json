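[
  {
    "name": "1",
    "types": [
      {
        "mean": 37.5,
        "sd": 3.8,
        "frequency": 0.3
      },
      {
        "mean": 60.0,
        "sd": 6.0,
        "frequency": 0.35
      },
      {
        "mean": 90.0,
        "sd": 9.0,
        "frequency": 0.25
      },
      {
        "mean": 135.0,
        "sd": 13.5,
        "frequency": 0.1
      }
    ]
  },
  {
    "name": "2",
    "types": [
      {
        "mean": 41.1,
        "sd": 7.0,
        "frequency": 0.3
      },
      {
        "mean": 65.7,
        "sd": 11.3,
        "frequency": 0.35
      },
      {
        "mean": 98.6,
        "sd": 16.9,
        "frequency": 0.25
      },
      {
        "mean": 147.9,
        "sd": 25.3,
        "frequency": 0.1
      }
    ]
  },
  {
    "name": "3",
    "types": [
      {
        "mean": 44.6,
        "sd": 10.8,
        "frequency": 0.3
      },
      {
        "mean": 71.4,
        "sd": 17.3,
        "frequency": 0.35
      },
      {
        "mean": 107.1,
        "sd": 26.0,
        "frequency": 0.25
      },
      {
        "mean": 160.7,
        "sd": 39.0,
        "frequency": 0.1
      }
    ]
  },
  {
    "name": "4",
    "types": [
      {
        "mean": 48.2,
        "sd": 15.2,
        "frequency": 0.3
      },
      {
        "mean": 77.1,
        "sd": 24.2,
        "frequency": 0.35
      },
      {
        "mean": 115.7,
        "sd": 36.4,
        "frequency": 0.25
      },
      {
        "mean": 173.6,
        "sd": 54.6,
        "frequency": 0.1
      }
    ]
  },
  {
    "name": "5",
    "types": [
      {
        "mean": 51.8,
        "sd": 20.0,
        "frequency": 0.3
      },
      {
        "mean": 82.9,
        "sd": 32.0,
        "frequency": 0.35
      },
      {
        "mean": 124.3,
        "sd": 47.9,
        "frequency": 0.25
      },
      {
        "mean": 186.4,
        "sd": 71.9,
        "frequency": 0.1
      }
    ]
  },
  {
    "name": "6",
    "types": [
      {
        "mean": 55.4,
        "sd": 25.3,
        "frequency": 0.3
      },
      {
        "mean": 88.6,
        "sd": 40.5,
        "frequency": 0.35
      },
      {
        "mean": 132.9,
        "sd": 60.7,
        "frequency": 0.25
      },
      {
        "mean": 199.3,
        "sd": 91.1,
        "frequency": 0.1
      }
    ]
  },
  {
    "name": "7",
    "types": [
      {
        "mean": 58.9,
        "sd": 31.1,
        "frequency": 0.3
      },
      {
        "mean": 94.3,
        "sd": 49.8,
        "frequency": 0.35
      },
      {
        "mean": 141.4,
        "sd": 74.8,
        "frequency": 0.25
      },
      {
        "mean": 212.1,
        "sd": 112.1,
        "frequency": 0.1
      }
    ]
  },
  {
    "name": "8",
    "types": [
      {
        "mean": 62.5,
        "sd": 37.5,
        "frequency": 0.3
      },
      {
        "mean": 100.0,
        "sd": 60.0,
        "frequency": 0.35
      },
      {
        "mean": 150.0,
        "sd": 90.0,
        "frequency": 0.25
      },
      {
        "mean": 225.0,
        "sd": 135.0,
        "frequency": 0.1
      }
    ]
  }
]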