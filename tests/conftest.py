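import pytest
from hypothesis import settings

from elusivegenes.taxonomy import load_taxonomy

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

SMALL_TAXONOMY_YAML = """
focal_species: human
focal_groups: [Primates, Rodentia, Carnivora, Chiroptera]
tree:
  name: Mammalia
  children:
    - name: Laurasiatheria
      children:
        - name: Carnivora
          species: [dog, cat]
        - name: Chiroptera
          species: [bat]
    - name: Euarchontoglires
      children:
        - name: Rodentia
          species: [mouse, rat]
        - name: Primates
          children:
            - name: Hominini
              species: [human, chimp]
            - gorilla
    - shrew
"""


@pytest.fixture(scope="session")
def small_taxonomy():
    """9 species, 4 focal groups, one ungrouped species (shrew)."""
    return load_taxonomy(SMALL_TAXONOMY_YAML)
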