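{
  "id": 2,
  "arena_bounds": [
    3.0,
    4.0
  ],
  "start_location": [
    2.6,
    3.7,
    0.0
  ],
  "boxes": [
    {
      "id": "T1",
      "center": [
        2.25,
        3.05,
        0.35
      ],
      "dims": [
        1.14,
        0.7,
        0.7
      ],
      "faces": {
        "+x": "covered",
        "-x": "covered",
        "+y": "covered",
        "-y": "covered",
        "+z": "covered",
        "-z": "covered"
      }
    },
    {
      "id": "T2",
      "center": [
        2.25,
        0.9,
        0.35
      ],
      "dims": [
        1.14,
        0.7,
        0.7
      ],
      "faces": {
        "+x": "covered",
        "-x": "covered",
        "+y": "covered",
        "-y": "covered",
        "+z": "covered",
        "-z": "covered"
      }
    },
    {
      "id": "T3",
      "center": [
        0.65,
        1.3,
        0.35
      ],
      "dims": [
        0.7,
        1.14,
        0.7
      ],
      "faces": {
        "+x": "covered",
        "-x": "covered",
        "+y": "covered",
        "-y": "covered",
        "+z": "covered",
        "-z": "covered"
      }
    },
    {
      "id": "C1",
      "center": [
        2.0,
        3.05,
        0.85
      ],
      "dims": [
        0.3,
        0.3,
        0.3
      ],
      "faces": {
        "+x": "covered",
        "-x": "open",
        "+y": "covered",
        "-y": "wire",
        "+z": "wire",
        "-z": "covered"
      }
    },
    {
      "id": "C2",
      "center": [
        2.3,
        3.05,
        0.85
      ],
      "dims": [
        0.3,
        0.3,
        0.3
      ],
      "faces": {
        "+x": "covered",
        "-x": "wire",
        "+y": "covered",
        "-y": "open",
        "+z": "wire",
        "-z": "covered"
      }
    },
    {
      "id": "C3",
      "center": [
        2.5,
        0.9,
        0.85
      ],
      "dims": [
        0.3,
        0.3,
        0.3
      ],
      "faces": {
        "+x": "covered",
        "-x": "open",
        "+y": "covered",
        "-y": "wire",
        "+z": "wire",
        "-z": "covered"
      }
    },
    {
      "id": "C4",
      "center": [
        2.5,
        0.9,
        1.15
      ],
      "dims": [
        0.3,
        0.3,
        0.3
      ],
      "faces": {
        "+x": "covered",
        "-x": "open",
        "+y": "covered",
        "-y": "wire",
        "+z": "wire",
        "-z": "covered"
      }
    },
    {
      "id": "C5",
      "center": [
        1.95,
        0.9,
        0.85
      ],
      "dims": [
        0.3,
        0.3,
        0.3
      ],
      "faces": {
        "+x": "covered",
        "-x": "wire",
        "+y": "open",
        "-y": "covered",
        "+z": "wire",
        "-z": "covered"
      }
    },
    {
      "id": "C6",
      "center": [
        0.65,
        0.9,
        0.85
      ],
      "dims": [
        0.3,
        0.3,
        0.3
      ],
      "faces": {
        "+x": "covered",
        "-x": "wire",
        "+y": "open",
        "-y": "covered",
        "+z": "wire",
        "-z": "covered"
      }
    }
  ]
}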