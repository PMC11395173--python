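{
  "name": "king_weakfish_whole_ice",
  "version": 1,
  "groups": [
    {
      "group_name": "overall aspect",
      "parameters": [
        {
          "parameter_name": "surface appearance",
          "descriptors": [
            {"description": "Intense glisten, characteristic pigmentation", "demerit": 0},
            {"description": "Glistening, more opaque colors", "demerit": 1},
            {"description": "Little glisten, depigmentation", "demerit": 2}
          ]
        },
        {
          "parameter_name": "meat firmness",
          "descriptors": [
            {"description": "Firm, little elastic", "demerit": 0},
            {"description": "Tender, signs of pressure", "demerit": 1}
          ]
        },
        {
          "parameter_name": "fins",
          "descriptors": [
            {"description": "Very elastic", "demerit": 0},
            {"description": "Little elastic", "demerit": 1},
            {"description": "No elasticity", "demerit": 2}
          ]
        }
      ]
    },
    {
      "group_name": "gills",
      "parameters": [
        {
          "parameter_name": "gill color",
          "descriptors": [
            {"description": "Bright red to dark red", "demerit": 0},
            {"description": "Less-bright red", "demerit": 1},
            {"description": "Less-bright red to pink", "demerit": 2}
          ]
        },
        {
          "parameter_name": "gill mucus",
          "descriptors": [
            {"description": "Little mucus, clear", "demerit": 0},
            {"description": "Consistent mucus, opaque", "demerit": 1},
            {"description": "Much mucus, opaque", "demerit": 2}
          ]
        },
        {
          "parameter_name": "gill odor",
          "descriptors": [
            {"description": "Algae (slightly wet sand)", "demerit": 0},
            {"description": "Neutral, less intense algae", "demerit": 1},
            {"description": "Slightly rancid", "demerit": 2}
          ]
        },
        {
          "parameter_name": "gill shape",
          "descriptors": [
            {"description": "Whole", "demerit": 0},
            {"description": "Slightly misshapen", "demerit": 1},
            {"description": "Misshapen", "demerit": 2}
          ]
        }
      ]
    },
    {
      "group_name": "eyes",
      "parameters": [
        {
          "parameter_name": "eyeball",
          "descriptors": [
            {"description": "Clear (transparent)", "demerit": 0},
            {"description": "Slightly opaque", "demerit": 1},
            {"description": "Milky, opaque", "demerit": 2}
          ]
        },
        {
          "parameter_name": "pupil",
          "descriptors": [
            {"description": "Bluish-black, well defined", "demerit": 0},
            {"description": "Foggy and defined", "demerit": 1},
            {"description": "Foggy and undefined", "demerit": 2}
          ]
        },
        {
          "parameter_name": "eye shape",
          "descriptors": [
            {"description": "Squashed (flat)", "demerit": 0},
            {"description": "Depressed (concave)", "demerit": 1}
          ]
        },
        {
          "parameter_name": "eye blood",
          "descriptors": [
            {"description": "Absent", "demerit": 0},
            {"description": "Slightly bloody", "demerit": 1}
          ]
        }
      ]
    },
    {
      "group_name": "anal area",
      "parameters": [
        {
          "parameter_name": "anal odor",
          "descriptors": [
            {"description": "Fresh (algae)", "demerit": 0},
            {"description": "Slightly rancid", "demerit": 1}
          ]
        },
        {
          "parameter_name": "anal condition",
          "descriptors": [
            {"description": "Closed", "demerit": 0},
            {"description": "Open", "demerit": 1}
          ]
        }
      ]
    }
  ]
}
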