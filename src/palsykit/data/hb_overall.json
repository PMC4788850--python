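{
 "description": "Overall House-Brackmann grade for concordant regional-grade triples (regional grades within one step of each other), an editable interpretation of the regional scale descriptions. Uniform mid-scale triples step up one grade (all regions mildly affected reads as moderate overall); discordant triples are resolved by the multinomial-regression fallback.",
 "rows": [
  {
   "forehead": 1,
   "eye": 1,
   "mouth": 1,
   "overall": 1
  },
  {
   "forehead": 1,
   "eye": 1,
   "mouth": 2,
   "overall": 2
  },
  {
   "forehead": 1,
   "eye": 2,
   "mouth": 1,
   "overall": 2
  },
  {
   "forehead": 1,
   "eye": 2,
   "mouth": 2,
   "overall": 2
  },
  {
   "forehead": 2,
   "eye": 1,
   "mouth": 1,
   "overall": 2
  },
  {
   "forehead": 2,
   "eye": 1,
   "mouth": 2,
   "overall": 2
  },
  {
   "forehead": 2,
   "eye": 2,
   "mouth": 1,
   "overall": 2
  },
  {
   "forehead": 2,
   "eye": 2,
   "mouth": 2,
   "overall": 3
  },
  {
   "forehead": 2,
   "eye": 2,
   "mouth": 3,
   "overall": 3
  },
  {
   "forehead": 2,
   "eye": 3,
   "mouth": 2,
   "overall": 3
  },
  {
   "forehead": 2,
   "eye": 3,
   "mouth": 3,
   "overall": 3
  },
  {
   "forehead": 3,
   "eye": 2,
   "mouth": 2,
   "overall": 3
  },
  {
   "forehead": 3,
   "eye": 2,
   "mouth": 3,
   "overall": 3
  },
  {
   "forehead": 3,
   "eye": 3,
   "mouth": 2,
   "overall": 3
  },
  {
   "forehead": 3,
   "eye": 3,
   "mouth": 3,
   "overall": 4
  },
  {
   "forehead": 3,
   "eye": 3,
   "mouth": 4,
   "overall": 4
  },
  {
   "forehead": 3,
   "eye": 4,
   "mouth": 3,
   "overall": 4
  },
  {
   "forehead": 3,
   "eye": 4,
   "mouth": 4,
   "overall": 4
  },
  {
   "forehead": 4,
   "eye": 3,
   "mouth": 3,
   "overall": 4
  },
  {
   "forehead": 4,
   "eye": 3,
   "mouth": 4,
   "overall": 4
  },
  {
   "forehead": 4,
   "eye": 4,
   "mouth": 3,
   "overall": 4
  },
  {
   "forehead": 4,
   "eye": 4,
   "mouth": 4,
   "overall": 5
  },
  {
   "forehead": 4,
   "eye": 4,
   "mouth": 5,
   "overall": 5
  },
  {
   "forehead": 4,
   "eye": 5,
   "mouth": 4,
   "overall": 5
  },
  {
   "forehead": 4,
   "eye": 5,
   "mouth": 5,
   "overall": 5
  },
  {
   "forehead": 5,
   "eye": 4,
   "mouth": 4,
   "overall": 5
  },
  {
   "forehead": 5,
   "eye": 4,
   "mouth": 5,
   "overall": 5
  },
  {
   "forehead": 5,
   "eye": 5,
   "mouth": 4,
   "overall": 5
  },
  {
   "forehead": 5,
   "eye": 5,
   "mouth": 5,
   "overall": 6
  },
  {
   "forehead": 5,
   "eye": 5,
   "mouth": 6,
   "overall": 6
  },
  {
   "forehead": 5,
   "eye": 6,
   "mouth": 5,
   "overall": 6
  },
  {
   "forehead": 5,
   "eye": 6,
   "mouth": 6,
   "overall": 6
  },
  {
   "forehead": 6,
   "eye": 5,
   "mouth": 5,
   "overall": 6
  },
  {
   "forehead": 6,
   "eye": 5,
   "mouth": 6,
   "overall": 6
  },
  {
   "forehead": 6,
   "eye": 6,
   "mouth": 5,
   "overall": 6
  },
  {
   "forehead": 6,
   "eye": 6,
   "mouth": 6,
   "overall": 6
  }
 ]
}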