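{
  "id": 3,
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
        0.75,
        0.95,
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
        1.5,
        2.6,
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
        2.35,
        0.95,
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
        0.5,
        0.95,
        0.85
      ],
      "dims": [
        0.3,
        0.3,
        0.3
      ],
      "faces": {
        "+x": "open",
        "-x": "covered",
        "+y": "covered",
        "-y": "wire",
        "+z": "wire",
        "-z": "covered"
      }
    },
    {
      "id": "C2",
      "center": [
        0.5,
        0.95,
        1.15
      ],
      "dims": [
        0.3,
        0.3,
        0.3
      ],
      "faces": {
        "+x": "open",
        "-x": "covered",
        "+y": "covered",
        "-y": "wire",
        "+z": "wire",
        "-z": "covered"
      }
    },
    {
      "id": "C3",
      "center": [
        2.35,
        1.2,
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
      "id": "C4",
      "center": [
        1.2,
        2.6,
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
      "id": "C5",
      "center": [
        1.5,
        2.6,
        0.85
      ],
      "dims": [
        0.3,
        0.3,
        0.3
      ],
      "faces": {
        "+x": "open",
        "-x": "covered",
        "+y": "covered",
        "-y": "wire",
        "+z": "wire",
        "-z": "covered"
      }
    },
    {
      "id": "C6",
      "center": [
        2.35,
        0.6,
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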